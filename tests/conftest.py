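import numpy as np
import pytest

from hylaxy.datamodel import (
    MISSING,
    NULL,
    Dataset,
    Family,
    Genotype,
    Individual,
    LocusDef,
)


def make_individual(ind_id, sex, role, genotypes, species="Ha", population="p1"):
    return Individual(ind_id, sex, role, species, population, genotypes)


def make_family(father_gts, mother_gts, offspring, fam_id="F1", species="Ha"):
    """offspring: list of (sex, genotypes) tuples."""
    father = make_individual(f"{fam_id}-fa", "M", "father", father_gts, species)
    mother = make_individual(f"{fam_id}-mo", "F", "mother", mother_gts, species)
    kids = [
        make_individual(f"{fam_id}-o{i}", sex, "offspring", gts, species)
        for i, (sex, gts) in enumerate(offspring, start=1)
    ]
    return Family(father, mother, kids)


def random_small_dataset(rng, n_families=2, max_offspring=4, with_null=True,
                         with_missing=True):
    """Random 2-locus dataset with small sibships, for exhaustive oracles."""
    loci = [LocusDef("A"), LocusDef("B")]
    pools = {"A": [100, 102, 104], "B": [200, 202, 204]}

    def allele(locus):
        if with_null and rng.random() < 0.12:
            return NULL
        return pools[locus][rng.integers(len(pools[locus]))]

    def genotype(locus, allow_missing):
        if allow_missing and with_missing and rng.random() < 0.10:
            return Genotype(MISSING, MISSING)
        return Genotype(allele(locus), allele(locus))

    families = []
    for j in range(n_families):
        fid = f"F{j+1}"
        fgts = {l: genotype(l, allow_missing=False) for l in pools}
        mgts = {l: genotype(l, allow_missing=False) for l in pools}

        def child(fg, mg, locus_rng):
            fa = fg.alleles[locus_rng.integers(2)]
            ma = mg.alleles[locus_rng.integers(2)]
            return Genotype(fa, ma)

        kids = []
        for k in range(int(rng.integers(1, max_offspring + 1))):
            gts = {}
            for l in pools:
                if with_missing and rng.random() < 0.10:
                    continue  # untyped at this locus (canonically unstored)
                gts[l] = child(fgts[l], mgts[l], rng)
            kids.append(("M" if rng.random() < 0.5 else "F", gts))
        families.append(make_family(fgts, mgts, kids, fam_id=fid))
    return Dataset(loci=loci, families=families)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
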