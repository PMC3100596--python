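"""Sex linkage from allele frequencies and Y-haplotype reconstruction.

On an XY pair with no male recombination, every male carries one Y-pool
allele per sex-linked locus; allele frequencies then differ between the
sexes, and sibships expose the paternal Y haplotype directly (the allele
every son received and no daughter did).  This module provides:

* a G-test of allele-frequency differences between sexes whose null is
  built by permuting sex labels across individuals — both alleles travel
  with their carrier, respecting within-individual dependence;
* exact Y-haplotype calls from families (assuming complete male linkage),
  with inconsistency flags where a son/daughter conflict hints at
  sex reversal, recombination, or a scoring error;
* population-level Y assignment from candidate Y alleles, with
  wildcard-tolerant counting of distinct multilocus Y haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    MISSING,
    NULL,
    Family,
    Genotype,
    _offspring_compatible,
    _transmissible,
)

#: Y-call sentinels (a concrete call is an allele size or NULL).
AMBIGUOUS = "ambiguous"
UNTYPED = "untyped"


# ---------------------------------------------------------------------------
# Sex differences in allele frequencies


@dataclass
class SexFreqResult:
    locus: str
    counts: dict  # sex -> {allele: count}
    g_statistic: float
    p: float
    n_perm: int

    @property
    def frequencies(self) -> dict:
        out = {}
        for sex, cts in self.counts.items():
            tot = sum(cts.values())
            out[sex] = {a: c / tot for a, c in cts.items()} if tot else {}
        return out


def _countable_alleles(g: Genotype):
    return [a for a in g.alleles if a is not MISSING and a is not NULL]


def _g_statistic(table: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) over an allele x sex count table."""
    table = table.astype(float)
    total = table.sum()
    if total == 0:
        return 0.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / E), 0.0)
    return float(2.0 * terms.sum())


def sex_allele_freq_test(adults, locus: str, n_perm: int = 1000,
                         seed: int = 0) -> SexFreqResult:
    """G-test of allelic differentiation between the sexes at one locus.

    ``adults`` is an iterable of individuals with known sex; null and
    missing alleles are uncounted.  The permutation null shuffles sex
    labels across individuals (n_perm label permutations); the p-value
    carries the +1 correction so it is never exactly zero.
    """
    carriers = []
    for ind in adults:
        if ind.sex not in ("M", "F"):
            continue
        alleles = _countable_alleles(ind.genotype(locus))
        if alleles:
            carriers.append((ind.sex, alleles))
    n_m = sum(1 for s, _ in carriers if s == "M")
    n_f = len(carriers) - n_m
    if n_m < 2 or n_f < 2:
        raise ValueError(
            f"need >=2 typed individuals per sex at {locus} (got {n_m} M, {n_f} F)"
        )
    allele_ids = sorted({a for _, al in carriers for a in al})
    index = {a: i for i, a in enumerate(allele_ids)}

    # per-individual count vectors, so labels can be permuted wholesale
    vecs = np.zeros((len(carriers), len(allele_ids)), dtype=np.int64)
    sexes = np.array([s == "M" for s, _ in carriers])
    for i, (_, alleles) in enumerate(carriers):
        for a in alleles:
            vecs[i, index[a]] += 1

    def table(is_male):
        return np.stack([vecs[is_male].sum(axis=0), vecs[~is_male].sum(axis=0)], axis=1)

    g_obs = _g_statistic(table(sexes))
    counts = {
        "M": {a: int(c) for a, c in zip(allele_ids, vecs[sexes].sum(axis=0)) if c},
        "F": {a: int(c) for a, c in zip(allele_ids, vecs[~sexes].sum(axis=0)) if c},
    }
    if len(allele_ids) < 2 or g_obs == 0.0:
        return SexFreqResult(locus, counts, g_obs, 1.0, 0)

    rng = np.random.default_rng(seed)
    hits = 0
    labels = sexes.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        if _g_statistic(table(labels)) >= g_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return SexFreqResult(locus, counts, g_obs, p, n_perm)


# ---------------------------------------------------------------------------
# Y haplotypes from sibships


@dataclass
class YHaplotypeCall:
    """Per-male multilocus Y call.

    ``calls`` maps locus to an allele size, NULL, ``"ambiguous"`` or
    ``"untyped"``; ``flags`` maps locus to a list of annotations
    (``inconsistent``, ``uninformative-homozygote``, ...).
    """

    male_id: str
    calls: dict
    provenance: str  # "sibship" | "population"
    flags: dict = field(default_factory=dict)

    def called_loci(self):
        return [
            l for l, c in self.calls.items() if c not in (AMBIGUOUS, UNTYPED)
        ]


def _paternal_allele_options(off, mother, locus):
    """Paternal alleles (of the father's two) each offspring could have
    received, resolving via the mother's genotype when possible."""
    obs = off.genotype(locus)
    if obs.is_untyped:
        return None  # uninformative
    mg = mother.genotype(locus)
    ys = _transmissible(mg)
    if ys is None:
        ys = [a for a in obs.alleles if a is not MISSING] + [NULL]
    return ys, obs


def infer_y_from_family(family: Family, loci=None) -> YHaplotypeCall:
    """Reconstruct the father's Y haplotype from his sibship.

    Assumes complete male linkage (theta_m = 0 at the loci; caller
    asserts).  Per locus the allele received by every (unambiguous) son and
    by no daughter is the Y call; a son-daughter conflict marks the locus
    ``inconsistent`` and the call ambiguous.
    """
    father, mother = family.father, family.mother
    if loci is None:
        loci = sorted(father.genotypes)
    calls, flags = {}, {}
    for locus in loci:
        fg = father.genotype(locus)
        if fg.has_missing:
            calls[locus] = UNTYPED
            continue
        f1, f2 = fg.alleles
        if f1 == f2:
            calls[locus] = AMBIGUOUS
            flags.setdefault(locus, []).append("uninformative-homozygote")
            continue
        son_alleles, daughter_alleles = set(), set()
        for off in family.offspring:
            opts = _paternal_allele_options(off, mother, locus)
            if opts is None:
                continue
            ys, obs = opts
            possible = {
                x for x in (f1, f2)
                if any(_offspring_compatible(obs, x, y) for y in ys)
            }
            if len(possible) == 0:
                flags.setdefault(locus, []).append("mendel-conflict")
                continue
            if len(possible) > 1:
                continue  # transmission ambiguous for this offspring
            (allele,) = possible
            if off.sex == "M":
                son_alleles.add(allele)
            elif off.sex == "F":
                daughter_alleles.add(allele)
        if not son_alleles:
            calls[locus] = AMBIGUOUS
            flags.setdefault(locus, []).append("no-informative-son")
            continue
        if len(son_alleles) > 1 or (son_alleles & daughter_alleles):
            calls[locus] = AMBIGUOUS
            flags.setdefault(locus, []).append("inconsistent")
            continue
        calls[locus] = next(iter(son_alleles))
    return YHaplotypeCall(father.id, calls, "sibship", flags)


# ---------------------------------------------------------------------------
# Population Y assignment


def assign_y_population(males, candidates: dict, loci=None) -> list:
    """Call the Y allele of each male from candidate Y-allele sets.

    ``candidates`` maps locus to the set of alleles known (from sibships
    and/or male-biased frequencies) to occur on Y chromosomes.  Per male
    and locus the call is the unique genotype allele in the candidate set;
    zero or two matches give an ambiguous call.  A homozygote for a
    candidate is called but flagged (the same allele could sit on his X).
    """
    if loci is None:
        loci = sorted(candidates)
    out = []
    for male in males:
        if male.sex != "M":
            raise ValueError(f"{male.id} is not male")
        calls, flags = {}, {}
        for locus in loci:
            g = male.genotype(locus)
            cset = set(candidates.get(locus, ()))
            if g.is_untyped or g.has_missing:
                calls[locus] = UNTYPED
                continue
            if not cset:
                calls[locus] = AMBIGUOUS
                flags.setdefault(locus, []).append("no-candidates")
                continue
            in_set = [a for a in dict.fromkeys(g.alleles) if a in cset]
            if len(in_set) == 1:
                calls[locus] = in_set[0]
                if g.alleles[0] == g.alleles[1]:
                    flags.setdefault(locus, []).append("uninformative-homozygote")
            else:
                calls[locus] = AMBIGUOUS
        out.append(YHaplotypeCall(male.id, calls, "population", flags))
    return out


def count_y_haplotypes(calls, loci=None):
    """Count distinct multilocus Y haplotypes, wildcard-tolerant.

    Ambiguous/untyped calls are wildcards: two haplotypes are distinct only
    if they conflict at a locus called in both.  Greedy agglomeration in a
    deterministic order (most-called males first); each cluster keeps a
    prototype whose wildcards fill in as compatible males join.

    Returns ``(n, clusters)`` with each cluster a dict
    ``{"prototype": {locus: allele}, "members": [male ids]}``.
    """
    calls = list(calls)
    if loci is None:
        loci = sorted({l for c in calls for l in c.calls})
    order = sorted(
        calls, key=lambda c: (-len(c.called_loci()), c.male_id)
    )
    clusters = []
    for call in order:
        concrete = {
            l: call.calls[l]
            for l in loci
            if call.calls.get(l, UNTYPED) not in (AMBIGUOUS, UNTYPED)
        }
        placed = False
        for cl in clusters:
            proto = cl["prototype"]
            if all(proto.get(l, None) in (None, a) for l, a in concrete.items()):
                proto.update(concrete)
                cl["members"].append(call.male_id)
                placed = True
                break
        if not placed:
            clusters.append({"prototype": dict(concrete), "members": [call.male_id]})
    return len(clusters), clusters
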