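"""Synthetic data with known truth.

Two generators feed the downstream analyses:

* :func:`simulate_pedigrees` builds family genotype datasets on an XY system:
  fathers carry one X-background and one Y-background haplotype, mothers two
  X haplotypes; meioses recombine between adjacent microsatellite loci with
  sex-specific fractions (zero in males, high in females, in the regime the
  analyses target), with stepwise mutation and heritable null alleles.

* :func:`simulate_genealogy` runs a structured coalescent for a sex-linked
  locus in one or three species: within a species, X-background and
  Y-background lineage pools coalesce separately, joined by an exchange rate
  ``r`` that models X-Y recombination in sex-reversed XY females.  Scenario
  presets reproduce the canonical expected genealogies: an autosomal marker,
  ancestral sex chromosomes with occasional X-Y recombination, ancestral sex
  chromosomes with recombination frozen since before the species split, and
  a recent Y arising by turnover from the ancestral X.

:func:`evolve_sequences` drops Jukes-Cantor sequences on a simulated
genealogy so the whole distance/tree/classification pipeline can be
exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datamodel import (
    NULL,
    Alignment,
    Dataset,
    Family,
    Genotype,
    Individual,
    LabeledTree,
    LocusDef,
    TipLabel,
)

SCENARIOS = (
    "autosomal",
    "recombining_ancestral",
    "frozen_ancestral",
    "turnover_from_X",
)


class ConfigError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data.

    Pedigree runs fill the genotype-side fields; genealogy runs fill
    ``tree`` and the lineage state history.  Everything downstream
    inference could be scored against is recorded.
    """

    # pedigree truth -------------------------------------------------------
    male_y: dict = field(default_factory=dict)  # male id -> tuple of Y alleles
    paternal_backgrounds: dict = field(default_factory=dict)  # off id -> tuple 'X'/'Y'
    paternal_recombs: dict = field(default_factory=dict)  # off id -> tuple of intervals
    maternal_recombs: dict = field(default_factory=dict)
    paternal_haplotypes: dict = field(default_factory=dict)  # off id -> tuple alleles
    maternal_haplotypes: dict = field(default_factory=dict)
    # genealogy truth ------------------------------------------------------
    tree: LabeledTree | None = None
    switch_events: list = field(default_factory=list)  # (time, tips, from, to, kind)
    tmrca: float | None = None

    def recombinant_fraction(self, interval: int, parent: str = "maternal") -> float:
        """Realized crossover fraction in one inter-locus interval."""
        recs = self.maternal_recombs if parent == "maternal" else self.paternal_recombs
        if not recs:
            raise ValueError("no pedigree truth recorded")
        hits = sum(1 for ivs in recs.values() if interval in ivs)
        return hits / len(recs)

    def truth_csv(self) -> str:
        """Per-offspring transmission truth as CSV text."""
        lines = ["offspring,paternal_background,paternal_recombs,maternal_recombs"]
        for oid in sorted(self.paternal_backgrounds):
            bg = "".join(self.paternal_backgrounds[oid])
            pr = ";".join(map(str, self.paternal_recombs[oid]))
            mr = ";".join(map(str, self.maternal_recombs[oid]))
            lines.append(f"{oid},{bg},{pr},{mr}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pedigree simulation


@dataclass
class PedigreeSimConfig:
    """Parameters for the family-genotype simulator.

    ``founder_freqs_x``/``founder_freqs_y`` give, per locus, the allele-size
    frequency spectrum of the X and Y chromosome pools from which founder
    haplotypes are drawn (linkage equilibrium within a pool).  ``theta_m``
    and ``theta_f`` are per-adjacent-interval recombination fractions; the
    male default is complete linkage, the female default free-ish
    recombination, matching the regime the sibship analyses dissect.
    """

    loci: list
    theta_f: list
    theta_m: list
    founder_freqs_x: list  # per locus: dict allele -> freq
    founder_freqs_y: list
    n_families: int = 20
    offspring_per_family: float = 20.0
    species: tuple = ("Ha",)
    population: str = "pop1"
    null_allele_freq: float | list = 0.0
    smm_mutation_rate: float | list = 0.0
    n_adult_males: int = 0
    n_adult_females: int = 0
    seed: int = 0

    def __post_init__(self):
        n = len(self.loci)
        if isinstance(self.species, str):
            self.species = (self.species,)
        if len(self.theta_f) != n - 1 or len(self.theta_m) != n - 1:
            raise ConfigError("theta_f/theta_m need one value per adjacent interval")
        for t in list(self.theta_f) + list(self.theta_m):
            if not 0.0 <= t <= 0.5:
                raise ConfigError(f"recombination fraction {t} outside [0, 0.5]")
        if len(self.founder_freqs_x) != n or len(self.founder_freqs_y) != n:
            raise ConfigError("founder frequency spectra need one entry per locus")
        for pool in (self.founder_freqs_x, self.founder_freqs_y):
            for freqs in pool:
                tot = sum(freqs.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ConfigError(f"founder allele frequencies sum to {tot}, not 1")
        self.null_allele_freq = self._per_locus(self.null_allele_freq, n)
        for q in self.null_allele_freq:
            if not 0.0 <= q < 1.0:
                raise ConfigError(f"null allele frequency {q} outside [0, 1)")
        self.smm_mutation_rate = self._per_locus(self.smm_mutation_rate, n)
        for u in self.smm_mutation_rate:
            if not 0.0 <= u < 1.0:
                raise ConfigError(f"mutation rate {u} outside [0, 1)")
        if self.n_families < 1:
            raise ConfigError("need at least one family")
        if self.offspring_per_family <= 0:
            raise ConfigError("offspring_per_family must be positive")

    @staticmethod
    def _per_locus(value, n):
        if isinstance(value, (int, float)):
            return [float(value)] * n
        value = list(value)
        if len(value) != n:
            raise ConfigError("per-locus parameter has wrong length")
        return value

    @classmethod
    def default(cls, n_loci=6, n_families=20, offspring_per_family=20.0,
                species=("Ha",), theta_f=None, theta_m=None,
                null_allele_freq=0.0, smm_mutation_rate=0.0,
                n_adult_males=0, n_adult_females=0, seed=0,
                n_alleles=6, motif_length=2):
        """A realistic default: 6 sex-linked dinucleotide loci, complete male
        linkage, female fractions of 0.4 per interval, 6 founder alleles per
        locus with a geometric-ish spectrum shared by the X pool and (shifted)
        Y pool."""
        loci = [LocusDef(f"L{i+1}", motif_length, "sex_linked") for i in range(n_loci)]
        if theta_f is None:
            theta_f = [0.4] * (n_loci - 1)
        if theta_m is None:
            theta_m = [0.0] * (n_loci - 1)
        base = np.array([0.30, 0.25, 0.18, 0.12, 0.09, 0.06][:n_alleles], float)
        base = base / base.sum()
        fx, fy = [], []
        for i in range(n_loci):
            sizes = [100 + 20 * i + motif_length * k for k in range(n_alleles)]
            fx.append({s: p for s, p in zip(sizes, base)})
            # Y pool: same sizes, reversed spectrum (overlapping X-Y allele
            # distributions, as on undifferentiated sex chromosomes)
            fy.append({s: p for s, p in zip(sizes, base[::-1])})
        return cls(
            loci=loci, theta_f=list(theta_f), theta_m=list(theta_m),
            founder_freqs_x=fx, founder_freqs_y=fy,
            n_families=n_families, offspring_per_family=offspring_per_family,
            species=species, null_allele_freq=null_allele_freq,
            smm_mutation_rate=smm_mutation_rate,
            n_adult_males=n_adult_males, n_adult_females=n_adult_females,
            seed=seed,
        )


def _draw_haplotype(freqs_per_locus, null_freq, rng):
    hap = []
    for freqs, q in zip(freqs_per_locus, null_freq):
        alleles = list(freqs)
        probs = np.array([freqs[a] for a in alleles])
        a = alleles[rng.choice(len(alleles), p=probs)]
        if q > 0 and rng.random() < q:
            a = NULL
        hap.append(a)
    return hap


def _meiosis(hap_a, hap_b, thetas, rng, start=None, mutation_rates=None, motifs=None):
    """One gamete from two parental haplotypes.

    Returns (gamete alleles, background per locus (0=hap_a, 1=hap_b),
    crossover interval indices).  ``start`` pins the background at the first
    locus (used to tie offspring sex to the paternal X/Y background).
    """
    n = len(hap_a)
    cur = int(rng.integers(2)) if start is None else start
    gamete, backgrounds, recombs = [], [], []
    for i in range(n):
        if i > 0:
            if thetas[i - 1] > 0 and rng.random() < thetas[i - 1]:
                cur = 1 - cur
                recombs.append(i - 1)
        backgrounds.append(cur)
        a = (hap_a, hap_b)[cur][i]
        if mutation_rates is not None and a is not NULL:
            if mutation_rates[i] > 0 and rng.random() < mutation_rates[i]:
                a = a + motifs[i] * (1 if rng.random() < 0.5 else -1)
        gamete.append(a)
    return gamete, backgrounds, recombs


def simulate_pedigrees(config: PedigreeSimConfig):
    """Simulate family groups on an XY system; returns (Dataset, SimTruth).

    Sons always receive the paternal Y-background haplotype at the first
    locus (the sex-determining region rides with it), daughters the
    X-background one; crossovers then switch backgrounds between adjacent
    loci with probability ``theta_m`` per interval.  Maternal gametes start
    on a random haplotype and recombine with ``theta_f``.  Null alleles are
    assigned to founder haplotypes and inherited; genotypes record them
    explicitly (the ``*`` convention of curated genotype tables).
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    families, adults = [], []
    n_loci = len(config.loci)
    motifs = [l.motif_length for l in config.loci]

    def male_individual(ind_id, role, species):
        x = _draw_haplotype(config.founder_freqs_x, config.null_allele_freq, rng)
        y = _draw_haplotype(config.founder_freqs_y, config.null_allele_freq, rng)
        gts = {
            config.loci[i].name: Genotype(x[i], y[i]) for i in range(n_loci)
        }
        ind = Individual(ind_id, "M", role, species, config.population, gts)
        truth.male_y[ind_id] = tuple(y)
        return ind, x, y

    def female_individual(ind_id, role, species):
        x1 = _draw_haplotype(config.founder_freqs_x, config.null_allele_freq, rng)
        x2 = _draw_haplotype(config.founder_freqs_x, config.null_allele_freq, rng)
        gts = {
            config.loci[i].name: Genotype(x1[i], x2[i]) for i in range(n_loci)
        }
        return Individual(ind_id, "F", role, species, config.population, gts), x1, x2

    for species in config.species:
        for j in range(1, config.n_families + 1):
            fid = f"{species}-F{j}"
            father, fx, fy = male_individual(f"{fid}-fa", "father", species)
            mother, mx1, mx2 = female_individual(f"{fid}-mo", "mother", species)
            n_off = 0
            while n_off == 0:
                n_off = int(rng.poisson(config.offspring_per_family))
            offspring = []
            for k in range(1, n_off + 1):
                oid = f"{fid}-O{k}"
                sex = "M" if rng.random() < 0.5 else "F"
                pat, pat_bg, pat_rec = _meiosis(
                    fx, fy, config.theta_m, rng,
                    start=(1 if sex == "M" else 0),
                    mutation_rates=config.smm_mutation_rate, motifs=motifs,
                )
                mat, _, mat_rec = _meiosis(
                    mx1, mx2, config.theta_f, rng,
                    mutation_rates=config.smm_mutation_rate, motifs=motifs,
                )
                gts = {
                    config.loci[i].name: Genotype(pat[i], mat[i])
                    for i in range(n_loci)
                }
                offspring.append(
                    Individual(oid, sex, "offspring", species, config.population, gts)
                )
                truth.paternal_backgrounds[oid] = tuple(
                    "Y" if b == 1 else "X" for b in pat_bg
                )
                truth.paternal_recombs[oid] = tuple(pat_rec)
                truth.maternal_recombs[oid] = tuple(mat_rec)
                truth.paternal_haplotypes[oid] = tuple(pat)
                truth.maternal_haplotypes[oid] = tuple(mat)
            families.append(Family(father, mother, offspring))
        for j in range(1, config.n_adult_males + 1):
            ind, _, _ = male_individual(f"{species}-am{j}", "adult", species)
            adults.append(ind)
        for j in range(1, config.n_adult_females + 1):
            ind, _, _ = female_individual(f"{species}-af{j}", "adult", species)
            adults.append(ind)

    return Dataset(loci=list(config.loci), families=families, adults=adults), truth


# ---------------------------------------------------------------------------
# Structured-coalescent genealogy simulation


@dataclass
class CoalSimConfig:
    """Parameters for the X/Y structured-coalescent simulator.

    Time runs backwards in generations.  ``n_x`` and ``n_y`` are haploid
    lineage-pool sizes (default ratio 3:1, the standard effective-size ratio
    of X to Y pools).  ``exchange_rate`` is the per-lineage, per-generation
    probability that a Y-background lineage traces back to the X pool (and
    symmetrically), i.e. the footprint of X-Y recombination in sex-reversed
    XY females.  Split-time defaults derive from divergence estimates of
    5.4 and 7.1 million years with a 2-year generation time.

    Scenario presets:

    * ``autosomal`` — a single pool per species (reference genealogy);
    * ``recombining_ancestral`` — X and Y pools exchanged at ``exchange_rate``
      throughout (ancestral sex chromosomes, occasional X-Y recombination);
    * ``frozen_ancestral`` — no exchange below the root; an ancestral rate
      ``r_anc`` applies above the root so the process terminates (the freeze
      postdates an exchanging ancestor by construction);
    * ``turnover_from_X`` — as frozen, but the reference species' Y lineages
      re-join its X pool at the recent time ``t_turn`` (a proto-Y derived
      from the ancestral X).
    """

    scenario: str = "recombining_ancestral"
    species: tuple = ("Ha", "Hi", "Hm")
    t_split_sister: float = 5.4e6 / 2.0  # generations; sister-pair split
    t_root: float = 7.1e6 / 2.0
    n_x: int = 3000
    n_y: int = 1000
    exchange_rate: float | None = None  # default 10 / n_y ("occasional")
    r_anc: float | None = None  # above-root rate for frozen presets; 1 / n_y
    samples: dict | None = None  # (species, gametolog) -> count
    t_turn: float | None = None
    mu: float = 1e-8
    seq_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if len(self.species) not in (1, 3):
            raise ConfigError("species tree must have one or three species")
        if len(self.species) == 3 and not (self.t_root > self.t_split_sister > 0):
            raise ConfigError("need t_root > t_split_sister > 0")
        if self.n_x < 1 or self.n_y < 1:
            raise ConfigError("pool sizes must be positive")
        if self.exchange_rate is None:
            self.exchange_rate = (
                10.0 / self.n_y if self.scenario == "recombining_ancestral" else 0.0
            )
        if self.exchange_rate < 0:
            raise ConfigError("exchange rate must be >= 0")
        if self.r_anc is None:
            self.r_anc = 1.0 / self.n_y
        if self.scenario == "frozen_ancestral":
            self.exchange_rate = 0.0
        if self.scenario == "turnover_from_X":
            self.exchange_rate = 0.0
            if self.t_turn is None:
                raise ConfigError("turnover_from_X requires t_turn")
            if not 0 < self.t_turn < (
                self.t_split_sister if len(self.species) == 3 else self.t_root
            ):
                raise ConfigError("t_turn must be recent (below the first split)")
        if self.samples is None:
            self.samples = {}
            for sp in self.species:
                self.samples[(sp, "X")] = 2
                self.samples[(sp, "Y")] = 2
        if self.scenario != "autosomal" and self.exchange_rate == 0 and self.r_anc == 0:
            raise ConfigError(
                "non-terminating configuration: two pools with no exchange anywhere"
            )


class _Lineage:
    __slots__ = ("node", "pop", "pool", "tips")

    def __init__(self, node, pop, pool, tips):
        self.node = node
        self.pop = pop
        self.pool = pool
        self.tips = tips  # frozenset of descendant tip names


def simulate_genealogy(config: CoalSimConfig):
    """Run the structured coalescent; returns (LabeledTree, SimTruth).

    Branch lengths are in generations.  ``SimTruth.switch_events`` records
    every pool switch as ``(time, descendant tips, from_pool, to_pool,
    kind)`` with kind ``"exchange"`` or ``"turnover"``; ``SimTruth.tmrca``
    is the root age.
    """
    rng = np.random.default_rng(config.seed)
    single = len(config.species) == 1
    ref = config.species[0]
    taxa = dendropy.TaxonNamespace()

    lineages = []
    for (sp, gam), count in sorted(config.samples.items()):
        if sp not in config.species:
            raise ConfigError(f"sample species {sp!r} not in species tree")
        for i in range(1, count + 1):
            label = str(TipLabel(sp, gam, str(i)))
            taxon = taxa.new_taxon(label)
            node = dendropy.Node(taxon=taxon)
            node.age = 0.0
            pool = "A" if config.scenario == "autosomal" else (
                gam if gam in ("X", "Y") else "X"
            )
            lineages.append(_Lineage(node, sp, pool, frozenset([label])))

    truth = SimTruth()
    pool_size = {"X": float(config.n_x), "Y": float(config.n_y),
                 "A": float(config.n_x)}

    # epoch boundaries, forward through the past
    events = []
    if config.scenario == "turnover_from_X":
        events.append((config.t_turn, "turnover"))
    if not single:
        events.append((config.t_split_sister, "split_sister"))
        events.append((config.t_root, "split_root"))
    events.sort()
    events.append((math.inf, "end"))

    def exchange_rate_at(t):
        if config.scenario == "autosomal":
            return 0.0
        above_root = t >= (config.t_root if not single else 0.0)
        if config.scenario == "recombining_ancestral":
            return config.exchange_rate
        # frozen / turnover: no exchange below the root, r_anc above
        if single:
            return config.r_anc
        return config.r_anc if above_root else 0.0

    t = 0.0
    ev_idx = 0
    while len(lineages) > 1:
        boundary, action = events[ev_idx] if ev_idx < len(events) else (math.inf, "end")
        r = exchange_rate_at(t)
        # per-(pop,pool) coalescence rates
        groups = {}
        for lin in lineages:
            groups.setdefault((lin.pop, lin.pool), []).append(lin)
        coal_rate = sum(
            len(g) * (len(g) - 1) / 2.0 / pool_size[pool]
            for (_, pool), g in groups.items()
        )
        switch_rate = r * len(lineages) if config.scenario != "autosomal" else 0.0
        total = coal_rate + switch_rate
        if total <= 0:
            if boundary is math.inf:
                raise ConfigError("non-terminating configuration reached at runtime")
            t = boundary
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= boundary:
                t = boundary
            else:
                t += wait
                if rng.random() < coal_rate / total:
                    keys = list(groups)
                    weights = np.array([
                        len(groups[k]) * (len(groups[k]) - 1) / 2.0 / pool_size[k[1]]
                        for k in keys
                    ])
                    k = keys[rng.choice(len(keys), p=weights / weights.sum())]
                    g = groups[k]
                    i, j = rng.choice(len(g), size=2, replace=False)
                    a, b = g[i], g[j]
                    parent = dendropy.Node()
                    parent.age = t
                    parent.add_child(a.node)
                    parent.add_child(b.node)
                    a.node.edge.length = t - a.node.age
                    b.node.edge.length = t - b.node.age
                    merged = _Lineage(parent, a.pop, a.pool, a.tips | b.tips)
                    lineages = [x for x in lineages if x is not a and x is not b]
                    lineages.append(merged)
                else:
                    lin = lineages[int(rng.integers(len(lineages)))]
                    other = "Y" if lin.pool == "X" else "X"
                    truth.switch_events.append(
                        (t, lin.tips, lin.pool, other, "exchange")
                    )
                    lin.pool = other
                continue
        # boundary reached
        if action == "turnover":
            for lin in lineages:
                if lin.pop == ref and lin.pool == "Y":
                    truth.switch_events.append((t, lin.tips, "Y", "X", "turnover"))
                    lin.pool = "X"
        elif action == "split_sister":
            s1, s2 = config.species[1], config.species[2]
            for lin in lineages:
                if lin.pop in (s1, s2):
                    lin.pop = "sister"
        elif action == "split_root":
            for lin in lineages:
                lin.pop = "anc"
        ev_idx += 1

    root = lineages[0].node
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    ltree = LabeledTree(tree)
    truth.tree = ltree
    truth.tmrca = root.age
    return ltree, truth


# ---------------------------------------------------------------------------
# Sequence evolution

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def evolve_sequences(tree: LabeledTree, mu: float, L: int, seed: int) -> Alignment:
    """Jukes-Cantor sequences on a genealogy with branch lengths in
    generations; ``mu`` is the substitution rate per site per generation.

    Along a branch of length ``t`` each site changes with probability
    ``(3/4)(1 - exp(-4 mu t / 3))``, to one of the three other bases
    uniformly; the root sequence is uniform over ACGT.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = {}
    root = tree.tree.seed_node
    seqs[id(root)] = rng.integers(4, size=L)
    records = []
    for node in tree.tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            t = node.edge.length or 0.0
            p = 0.75 * (1.0 - math.exp(-4.0 * mu * t / 3.0))
            parent_seq = seqs[id(node.parent_node)].copy()
            if p > 0:
                hit = rng.random(L) < p
                n_hit = int(hit.sum())
                if n_hit:
                    # jump to one of the 3 other bases uniformly
                    parent_seq[hit] = (
                        parent_seq[hit] + rng.integers(1, 4, size=n_hit)
                    ) % 4
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            seq = "".join("ACGT"[b] for b in seqs[id(node)])
            records.append((TipLabel.parse(node.taxon.label), seq))
    return Alignment(records)
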