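"""Sex-specific two-point linkage analysis from sibships.

The central object is the two-locus family likelihood
``L(theta_m, theta_f)``: for each double-heterozygous parent the unknown
linkage phase is summed out (prior 1/2 per phase, constant across the
sibship), and each offspring's unphased genotype is summed over the
parental transmissions compatible with it.  The father's transmissions
recombine with ``theta_m``, the mother's with ``theta_f`` — the sexes are
estimated jointly but freely, which is what exposes complete male linkage
next to free female recombination on undifferentiated sex chromosomes.

On top of the likelihood sit the joint MLE with per-sex LOD scores,
Morton's M likelihood-ratio heterogeneity test across datasets (chi-square
or permutation reference), dataset pooling, and exhaustive-order map
construction under the Haldane map function.

Missing calls are marginalized.  A null allele is an inheritable allele in
the likelihood when a parent's genotype records one (the ``*`` convention);
an offspring whose genotype is incompatible with every parental
transmission (suspected dropout or scoring error) is treated as missing at
that locus pair rather than zeroing the family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .datamodel import (
    MISSING,
    Dataset,
    Family,
    Genotype,
    Individual,
    _offspring_compatible,
)

THETA_MAX = 0.5


# ---------------------------------------------------------------------------
# Family likelihood profiles


def _fully_typed(parent: Individual, locusA: str, locusB: str) -> bool:
    gA, gB = parent.genotype(locusA), parent.genotype(locusB)
    return not (gA.has_missing or gB.has_missing)


def _double_het(parent: Individual, locusA: str, locusB: str) -> bool:
    return (
        _fully_typed(parent, locusA, locusB)
        and parent.genotype(locusA).is_het
        and parent.genotype(locusB).is_het
    )


def _free_candidates(obs: Genotype):
    """Transmitted-allele candidates for an untyped parent."""
    from .datamodel import NULL

    cands = [a for a in obs.alleles if a is not MISSING]
    cands.append(NULL)
    return cands


class _FamilyPairProfile:
    """Precomputed sufficient structure of one family for one locus pair.

    For a fully typed parent the four ordered gametes (allele at A from
    haplotype i, allele at B from haplotype j) split into parental and
    recombinant classes under each phase; per offspring only the 2x2 (or
    smaller) count matrix ``S[class_father, class_mother]`` of compatible
    gamete combinations is needed, so the likelihood is a product of
    bilinear forms in ((1-theta)/2, theta/2).
    """

    def __init__(self, family: Family, locusA: str, locusB: str):
        self.father_typed = _fully_typed(family.father, locusA, locusB)
        self.mother_typed = _fully_typed(family.mother, locusA, locusB)
        self.father_het = _double_het(family.father, locusA, locusB)
        self.mother_het = _double_het(family.mother, locusA, locusB)
        f_phases = (0, 1) if self.father_het else (0,)
        m_phases = (0, 1) if self.mother_het else (0,)
        self.phase_weight = 1.0 / (len(f_phases) * len(m_phases))
        self.n_inf_m = 0
        self.n_inf_f = 0
        self.dropout_marginalized = 0

        fgam = self._gametes(family.father, locusA, locusB)
        mgam = self._gametes(family.mother, locusA, locusB)

        # per phase combo: dict S-matrix bytes -> (S, multiplicity)
        self.combos = []
        per_combo_S = {pc: {} for pc in itertools.product(f_phases, m_phases)}
        for off in family.offspring:
            oA, oB = off.genotype(locusA), off.genotype(locusB)
            if oA.is_untyped and oB.is_untyped:
                continue
            typed_both = not (oA.has_missing or oB.has_missing)
            if typed_both and self.father_het:
                self.n_inf_m += 1
            if typed_both and self.mother_het:
                self.n_inf_f += 1
            M = self._match_matrix(oA, oB, fgam, mgam)
            if not M.any():
                self.dropout_marginalized += 1
                continue
            for pf, pm in per_combo_S:
                S = self._class_matrix(M, fgam, mgam, pf, pm)
                key = S.tobytes()
                if key in per_combo_S[(pf, pm)]:
                    per_combo_S[(pf, pm)][key][1] += 1
                else:
                    per_combo_S[(pf, pm)][key] = [S, 1]
        for pc, d in per_combo_S.items():
            self.combos.append([(S, mult) for S, mult in d.values()])

    @staticmethod
    def _gametes(parent: Individual, locusA: str, locusB: str):
        """Ordered gametes (i, j): allele i at A with allele j at B.

        Returns None for an untyped parent (transmission unconstrained).
        """
        if not _fully_typed(parent, locusA, locusB):
            return None
        gA, gB = parent.genotype(locusA), parent.genotype(locusB)
        return [
            ((i, j), (gA.alleles[i], gB.alleles[j]))
            for i in (0, 1)
            for j in (0, 1)
        ]

    @staticmethod
    def _match_matrix(oA, oB, fgam, mgam):
        f_opts = fgam if fgam is not None else [None]
        m_opts = mgam if mgam is not None else [None]
        M = np.zeros((len(f_opts), len(m_opts)), dtype=np.int64)
        for a, fo in enumerate(f_opts):
            for b, mo in enumerate(m_opts):
                fa_cands = [fo[1]] if fo is not None else None
                mo_cands = [mo[1]] if mo is not None else None
                fA = [fo[1][0]] if fo is not None else _free_candidates(oA)
                mA = [mo[1][0]] if mo is not None else _free_candidates(oA)
                fB = [fo[1][1]] if fo is not None else _free_candidates(oB)
                mB = [mo[1][1]] if mo is not None else _free_candidates(oB)
                okA = any(
                    _offspring_compatible(oA, x, y) for x in fA for y in mA
                )
                okB = any(
                    _offspring_compatible(oB, x, y) for x in fB for y in mB
                )
                M[a, b] = 1 if (okA and okB) else 0
        return M

    @staticmethod
    def _class_matrix(M, fgam, mgam, phase_f, phase_m):
        """Collapse the gamete-level match matrix to recombination classes.

        Class 0 = parental, 1 = recombinant under the given phase; a free
        (untyped) parent has the single class 0 with weight 1.
        """

        def classes(gam, phase):
            if gam is None:
                return [0]
            return [0 if ((i ^ j) == phase) else 1 for (i, j), _ in gam]

        fc = classes(fgam, phase_f)
        mc = classes(mgam, phase_m)
        nf = 1 if fgam is None else 2
        nm = 1 if mgam is None else 2
        S = np.zeros((nf, nm), dtype=np.int64)
        for a, ca in enumerate(fc):
            for b, cb in enumerate(mc):
                S[ca, cb] += M[a, b]
        return S

    def loglik(self, theta_m, theta_f):
        """Log-likelihood surface over arrays of theta values.

        ``theta_m`` and ``theta_f`` are 1-D arrays; returns an array of
        shape ``(len(theta_m), len(theta_f))``.
        """
        tm = np.atleast_1d(np.asarray(theta_m, dtype=float))
        tf = np.atleast_1d(np.asarray(theta_f, dtype=float))
        if np.any((tm < 0) | (tm > 0.5)) or np.any((tf < 0) | (tf > 0.5)):
            raise ValueError("theta values must lie in [0, 0.5]")
        wf = (
            np.stack([(1 - tm) / 2, tm / 2], axis=1)
            if self.father_typed
            else np.ones((len(tm), 1))
        )
        wm = (
            np.stack([(1 - tf) / 2, tf / 2], axis=1)
            if self.mother_typed
            else np.ones((len(tf), 1))
        )
        terms = []
        with np.errstate(divide="ignore"):
            for combo in self.combos:
                total = np.zeros((len(tm), len(tf)))
                for S, mult in combo:
                    T = wf @ (S @ wm.T)
                    total += mult * np.log(T)
                terms.append(total)
        if len(terms) == 1:
            return terms[0] + math.log(self.phase_weight)
        return logsumexp(np.stack(terms), axis=0) + math.log(self.phase_weight)


def family_two_point_loglik(family: Family, locusA: str, locusB: str,
                            theta_m: float, theta_f: float) -> float:
    """Two-locus log-likelihood of one sibship at given recombination
    fractions (natural log).  Sums over the unknown phase of each
    double-heterozygous parent and over transmissions consistent with each
    offspring's unphased genotype."""
    prof = _FamilyPairProfile(family, locusA, locusB)
    return float(prof.loglik([theta_m], [theta_f])[0, 0])


def _dataset_profiles(dataset: Dataset, locusA: str, locusB: str):
    if locusA not in dataset.locus_names or locusB not in dataset.locus_names:
        raise KeyError(f"locus pair ({locusA!r}, {locusB!r}) not in dataset")
    return [_FamilyPairProfile(fam, locusA, locusB) for fam in dataset.families]


def two_point_loglik(dataset: Dataset, locusA: str, locusB: str,
                     theta_m, theta_f):
    """Summed family log-likelihood; accepts scalars or 1-D grids.

    With array arguments, returns the full surface of shape
    ``(len(theta_m), len(theta_f))`` — the workhorse for grid oracles.
    """
    profiles = _dataset_profiles(dataset, locusA, locusB)
    tm = np.atleast_1d(np.asarray(theta_m, dtype=float))
    tf = np.atleast_1d(np.asarray(theta_f, dtype=float))
    total = np.zeros((len(tm), len(tf)))
    for p in profiles:
        total += p.loglik(tm, tf)
    if np.isscalar(theta_m) and np.isscalar(theta_f):
        return float(total[0, 0])
    return total


# ---------------------------------------------------------------------------
# Two-point estimation


@dataclass
class TwoPointEstimate:
    locusA: str
    locusB: str
    theta_m: float  # NaN when no informative male meioses
    theta_f: float
    lnL_max: float
    lod_m: float
    lod_f: float
    n_inf_m: int
    n_inf_f: int

    def __post_init__(self):
        for lod in (self.lod_m, self.lod_f):
            if not math.isnan(lod) and lod < -1e-9:
                raise ValueError("LOD scores must be >= 0")


def _surface_argmax(surface, tm, tf):
    i, j = np.unravel_index(int(np.argmax(surface)), surface.shape)
    return tm[i], tf[j], surface[i, j]


def estimate_two_point(dataset: Dataset, locusA: str, locusB: str,
                       coarse_step: float = 0.01,
                       fine_step: float = 0.001) -> TwoPointEstimate:
    """Joint MLE of (theta_m, theta_f) on [0, 0.5]^2 with per-sex LOD scores.

    A coarse grid locates the optimum, a local fine grid (default step
    0.001) pins it down; a sex with no informative meioses gets NaN for its
    fraction and LOD, the "NA" convention of recombination-rate tables.
    """
    profiles = _dataset_profiles(dataset, locusA, locusB)
    n_inf_m = sum(p.n_inf_m for p in profiles)
    n_inf_f = sum(p.n_inf_f for p in profiles)
    if n_inf_m == 0 and n_inf_f == 0:
        raise ValueError(
            f"no informative meioses for either sex at ({locusA}, {locusB})"
        )

    def surface(tm, tf):
        total = np.zeros((len(tm), len(tf)))
        for p in profiles:
            total += p.loglik(tm, tf)
        return total

    coarse_m = np.linspace(0.0, THETA_MAX, int(round(THETA_MAX / coarse_step)) + 1)
    coarse_f = coarse_m
    s = surface(coarse_m, coarse_f)
    tm0, tf0, _ = _surface_argmax(s, coarse_m, coarse_f)

    def refine_axis(center):
        lo = max(0.0, center - coarse_step)
        hi = min(THETA_MAX, center + coarse_step)
        n = int(round((hi - lo) / fine_step)) + 1
        return np.linspace(lo, hi, n)

    fine_m, fine_f = refine_axis(tm0), refine_axis(tf0)
    s_fine = surface(fine_m, fine_f)
    theta_m, theta_f, lnL_max = _surface_argmax(s_fine, fine_m, fine_f)

    def lod(sex):
        if sex == "m":
            alt = surface(np.array([THETA_MAX]), np.array([theta_f]))[0, 0]
        else:
            alt = surface(np.array([theta_m]), np.array([THETA_MAX]))[0, 0]
        return max(0.0, (lnL_max - alt) / math.log(10.0))

    return TwoPointEstimate(
        locusA=locusA,
        locusB=locusB,
        theta_m=theta_m if n_inf_m > 0 else math.nan,
        theta_f=theta_f if n_inf_f > 0 else math.nan,
        lnL_max=float(lnL_max),
        lod_m=lod("m") if n_inf_m > 0 else math.nan,
        lod_f=lod("f") if n_inf_f > 0 else math.nan,
        n_inf_m=n_inf_m,
        n_inf_f=n_inf_f,
    )


# ---------------------------------------------------------------------------
# Morton's M heterogeneity test


@dataclass
class HetTestResult:
    statistic: float
    df: int
    p: float
    sex: str
    p_perm: float | None = None
    theta_common: float = math.nan
    theta_groups: list = field(default_factory=list)

    def __post_init__(self):
        if self.statistic < -1e-9:
            raise ValueError("heterogeneity statistic must be >= 0")
        self.statistic = max(0.0, self.statistic)


def _profile_curves(fam_surfaces, bounds, sex):
    """Per-group profile log-likelihood over the tested sex's theta grid.

    ``fam_surfaces`` stacks per-family surfaces (axis 1 = theta_m grid,
    axis 2 = theta_f grid); the free sex is profiled out by maximization.
    """
    free_axis = 1 if sex == "F" else 2  # maximize over the other sex
    return [
        fam_surfaces[bounds[i]:bounds[i + 1]].sum(axis=0).max(axis=free_axis - 1)
        for i in range(len(bounds) - 1)
    ]


def _grid_lambda(curves):
    unconstr = sum(float(c.max()) for c in curves)
    constr = float(np.sum(np.stack(curves), axis=0).max())
    return max(0.0, 2.0 * (unconstr - constr))


def mtest(groups, locusA: str, locusB: str, sex: str | None = None,
          n_perm: int = 0, seed: int = 0,
          grid_step: float = 0.005):
    """Morton's M-test of recombination-fraction heterogeneity across
    datasets.

    For the tested sex, ``Lambda = 2 [sum_i max lnL_i - max over a common
    theta]`` with the other sex's fraction free per group in both terms;
    all maxima are taken on a shared theta grid (default step 0.005), which
    keeps Lambda >= 0 by construction.  ``groups`` is a list of
    :class:`Dataset`; returns a :class:`HetTestResult` for the requested
    sex, or a dict with both sexes when ``sex`` is None.  The chi-square
    reference uses ``k - 1`` degrees of freedom; because boundary MLEs
    (theta = 0) make it conservative, a permutation reference (families
    reallocated among groups, group sizes kept) is available via
    ``n_perm``.
    """
    if sex is None:
        return {
            s: mtest(groups, locusA, locusB, s, n_perm, seed, grid_step)
            for s in ("M", "F")
        }
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    k = len(groups)
    if k == 1:
        return HetTestResult(0.0, 0, 1.0, sex)
    all_profiles = [_dataset_profiles(ds, locusA, locusB) for ds in groups]
    attr = "n_inf_m" if sex == "M" else "n_inf_f"
    for i, profs in enumerate(all_profiles):
        if sum(getattr(p, attr) for p in profs) == 0:
            raise ValueError(
                f"group {i} has no informative {sex} meioses for ({locusA}, {locusB})"
            )
    tgrid = np.linspace(0.0, THETA_MAX, int(round(THETA_MAX / grid_step)) + 1)
    flat = [p for profs in all_profiles for p in profs]
    fam_surfaces = np.stack([p.loglik(tgrid, tgrid) for p in flat])
    sizes = [len(profs) for profs in all_profiles]
    bounds = np.cumsum([0] + sizes)

    curves = _profile_curves(fam_surfaces, bounds, sex)
    lam = _grid_lambda(curves)
    theta_groups = [float(tgrid[int(np.argmax(c))]) for c in curves]
    theta_c = float(tgrid[int(np.argmax(np.sum(np.stack(curves), axis=0)))])
    df = k - 1
    p = float(stats.chi2.sf(lam, df)) if lam > 0 else 1.0

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            order = rng.permutation(len(flat))
            lam_p = _grid_lambda(_profile_curves(fam_surfaces[order], bounds, sex))
            if lam_p >= lam - 1e-12:
                hits += 1
        p_perm = (1 + hits) / (1 + n_perm)
    return HetTestResult(lam, df, p, sex, p_perm, theta_c, theta_groups)


# ---------------------------------------------------------------------------
# Pooling


def pool_datasets(groups) -> Dataset:
    """Concatenate datasets sharing the same loci (the "merge" operation).

    Species/population provenance stays on individuals; colliding ids (as
    when a dataset is pooled with itself) get a ``~g<i>`` suffix.
    """
    if not groups:
        raise ValueError("nothing to pool")
    loci = groups[0].loci
    for ds in groups[1:]:
        if ds.loci != loci:
            raise ValueError("cannot pool datasets with conflicting locus definitions")
    seen = set()
    families, adults = [], []

    def unique(ind: Individual, gi: int) -> Individual:
        new_id = ind.id
        if new_id in seen:
            new_id = f"{ind.id}~g{gi}"
        seen.add(new_id)
        return Individual(
            new_id, ind.sex, ind.role, ind.species, ind.population,
            dict(ind.genotypes),
        )

    for gi, ds in enumerate(groups):
        for fam in ds.families:
            families.append(
                Family(
                    unique(fam.father, gi),
                    unique(fam.mother, gi),
                    [unique(o, gi) for o in fam.offspring],
                )
            )
        for ad in ds.adults:
            adults.append(unique(ad, gi))
    return Dataset(loci=list(loci), families=families, adults=adults)


# ---------------------------------------------------------------------------
# Map construction


def haldane_cm(theta: float) -> float:
    """Haldane map distance in centimorgans: d = -50 ln(1 - 2 theta)."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must be in [0, 0.5) for a finite Haldane distance")
    return -50.0 * math.log(1.0 - 2.0 * theta)


def haldane_theta(cm: float) -> float:
    """Inverse Haldane map function."""
    if cm < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-cm / 50.0))


def haldane_compose(t1: float, t2: float) -> float:
    """Recombination fraction across two adjacent intervals (no interference)."""
    return t1 * (1 - t2) + t2 * (1 - t1)


@dataclass
class LinkageMap:
    loci: list  # best order, canonical (first name < last name)
    interval_theta_f: list
    interval_theta_m: list
    positions_f_cm: list  # cumulative, female
    positions_m_cm: list
    objective_cm: float  # summed female Haldane lengths of the best order
    runner_up_gap_cm: float
    capped_intervals: list  # interval indices where theta_f >= 0.5 was capped

    def __post_init__(self):
        for pos in (self.positions_f_cm, self.positions_m_cm):
            if any(b < a - 1e-9 for a, b in zip(pos, pos[1:])):
                raise ValueError("map positions must be non-decreasing")


THETA_CAP = 0.49


def build_map(dataset: Dataset, loci=None,
              estimates: dict | None = None) -> LinkageMap:
    """Best locus order by exhaustive search (orders identified up to
    reversal), minimizing the summed female Haldane length of adjacent
    intervals; ties broken lexicographically by the locus-name tuple.

    ``estimates`` may supply precomputed :class:`TwoPointEstimate`s keyed by
    frozenset({locusA, locusB}).
    """
    if loci is None:
        loci = list(dataset.locus_names)
    if len(loci) < 2:
        raise ValueError("a map needs at least two loci")
    if len(loci) > 10:
        raise ValueError("exhaustive order search is limited to 10 loci")
    if estimates is None:
        estimates = {}
        for a, b in itertools.combinations(loci, 2):
            estimates[frozenset((a, b))] = estimate_two_point(dataset, a, b)

    def interval_cm(a, b):
        est = estimates[frozenset((a, b))]
        t = est.theta_f
        if math.isnan(t):
            return math.inf, t, False
        capped = False
        if t >= THETA_CAP:
            t, capped = THETA_CAP, True
        return haldane_cm(t), t, capped

    scored = []
    for perm in itertools.permutations(loci):
        if perm[0] > perm[-1]:  # orders are equivalent up to reversal
            continue
        total = 0.0
        for a, b in zip(perm, perm[1:]):
            cm, _, _ = interval_cm(a, b)
            total += cm
            if math.isinf(total):
                break
        scored.append((total, perm))
    scored.sort(key=lambda kv: (kv[0], kv[1]))
    best_total, best = scored[0]
    if math.isinf(best_total):
        raise ValueError("no order has estimable female fractions on all intervals")
    gap = (scored[1][0] - best_total) if len(scored) > 1 else math.inf

    itf, itm, capped_idx = [], [], []
    pos_f, pos_m = [0.0], [0.0]
    for idx, (a, b) in enumerate(zip(best, best[1:])):
        est = estimates[frozenset((a, b))]
        cm_f, tf_used, capped = interval_cm(a, b)
        if capped:
            capped_idx.append(idx)
        itf.append(est.theta_f)
        itm.append(est.theta_m)
        pos_f.append(pos_f[-1] + cm_f)
        tm = est.theta_m
        if math.isnan(tm):
            cm_m = 0.0  # male side unassessable: contributes no length
        else:
            cm_m = haldane_cm(min(tm, THETA_CAP))
        pos_m.append(pos_m[-1] + cm_m)
    return LinkageMap(
        loci=list(best),
        interval_theta_f=itf,
        interval_theta_m=itm,
        positions_f_cm=pos_f,
        positions_m_cm=pos_m,
        objective_cm=best_total,
        runner_up_gap_cm=gap,
        capped_intervals=capped_idx,
    )
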