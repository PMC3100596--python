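"""Shared domain types and file I/O.

Genotypes are microsatellite fragment sizes in integer base pairs.  Two
special allele states are distinguished throughout: :data:`NULL`, a
non-amplifying (null) allele written ``*`` in genotype tables, and
:data:`MISSING`, written ``NA``, meaning no call was made.  A null allele is
real and inheritable; a missing call carries no information.

Trees and alignments carry structured tip labels of the form
``species|gametolog|individual[|clone]`` so that downstream clustering
analyses can ask "do alleles group by species or by gametolog?".
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class _AlleleState:
    """Singleton sentinel for the NULL / MISSING allele states."""

    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: Non-amplifying (null) allele; inheritable, written ``*``.
NULL = _AlleleState("NULL")
#: No genotype call; uninformative, written ``NA``.
MISSING = _AlleleState("MISSING")

NULL_TOKEN = "*"
MISSING_TOKEN = "NA"

SEXES = ("M", "F", "U")
ROLES = ("father", "mother", "offspring", "adult")
GAMETOLOGS = ("X", "Y", "autosomal", "unknown")
LOCUS_CLASSES = ("sex_linked", "autosomal", "unknown")

Allele = object  # int | NULL | MISSING


def _allele_sort_key(a):
    if a is MISSING:
        return (2, 0)
    if a is NULL:
        return (1, 0)
    return (0, a)


def format_allele(a) -> str:
    if a is NULL:
        return NULL_TOKEN
    if a is MISSING:
        return MISSING_TOKEN
    return str(a)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles at one locus."""

    allele1: Allele
    allele2: Allele

    def __post_init__(self):
        a, b = sorted((self.allele1, self.allele2), key=_allele_sort_key)
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    @property
    def alleles(self) -> tuple:
        return (self.allele1, self.allele2)

    @property
    def is_untyped(self) -> bool:
        return self.allele1 is MISSING and self.allele2 is MISSING

    @property
    def has_missing(self) -> bool:
        return self.allele1 is MISSING or self.allele2 is MISSING

    @property
    def has_null(self) -> bool:
        return self.allele1 is NULL or self.allele2 is NULL

    @property
    def is_het(self) -> bool:
        """Heterozygous on its face (two distinct non-missing states)."""
        return (
            not self.has_missing
            and self.allele1 != self.allele2
        )

    def __repr__(self) -> str:
        return f"{format_allele(self.allele1)}/{format_allele(self.allele2)}"


UNTYPED = Genotype(MISSING, MISSING)


@dataclass(frozen=True)
class LocusDef:
    name: str
    motif_length: int = 2
    assumed_class: str = "unknown"

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if self.assumed_class not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {self.assumed_class!r}")


@dataclass
class Individual:
    id: str
    sex: str
    role: str
    species: str = ""
    population: str = ""
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for individual {self.id}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for individual {self.id}")
        if self.role == "father" and self.sex != "M":
            raise ValueError(f"father {self.id} must have sex M")
        if self.role == "mother" and self.sex != "F":
            raise ValueError(f"mother {self.id} must have sex F")

    def genotype(self, locus: str) -> Genotype:
        return self.genotypes.get(locus, UNTYPED)


@dataclass
class Family:
    father: Individual
    mother: Individual
    offspring: list

    def __post_init__(self):
        if self.father.sex != "M":
            raise ValueError("father must have sex M")
        if self.mother.sex != "F":
            raise ValueError("mother must have sex F")
        if len(self.offspring) < 1:
            raise ValueError("a family needs at least one offspring")

    @property
    def members(self) -> list:
        return [self.father, self.mother, *self.offspring]

    @property
    def sons(self) -> list:
        return [o for o in self.offspring if o.sex == "M"]

    @property
    def daughters(self) -> list:
        return [o for o in self.offspring if o.sex == "F"]


@dataclass
class Dataset:
    loci: list
    families: list = field(default_factory=list)
    adults: list = field(default_factory=list)

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in Dataset")
        known = set(names)
        for ind in self.all_individuals():
            unknown = set(ind.genotypes) - known
            if unknown:
                raise ValueError(
                    f"individual {ind.id} has genotypes at undeclared loci {sorted(unknown)}"
                )
        ids = [i.id for i in self.all_individuals()]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in Dataset")

    @property
    def locus_names(self) -> list:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in dataset")

    def all_individuals(self):
        for fam in self.families:
            yield fam.father
            yield fam.mother
            yield from fam.offspring
        yield from self.adults

    def all_adults(self):
        """Parents plus unrelated adults (the population sample)."""
        for fam in self.families:
            yield fam.father
            yield fam.mother
        yield from self.adults

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.families == other.families
            and self.adults == other.adults
        )


# ---------------------------------------------------------------------------
# Mendelian validation


@dataclass(frozen=True)
class MendelViolation:
    family_father_id: str
    offspring_id: str
    locus: str
    detail: str


def _transmissible(g: Genotype) -> list | None:
    """Alleles a parent with observed genotype ``g`` could transmit.

    ``None`` means unconstrained (a missing call tells us nothing).  An
    apparent homozygote may hide a null allele, so ``A/A`` can transmit
    ``A`` or ``NULL``.
    """
    if g.has_missing:
        return None
    a, b = g.alleles
    if a is NULL and b is NULL:
        return [NULL]
    if b is NULL:
        return [a, NULL]
    if a == b:
        return [a, NULL]
    return [a, b]


def _offspring_compatible(obs: Genotype, x, y) -> bool:
    """Is observed genotype ``obs`` consistent with true allele pair {x, y}?"""
    if obs.is_untyped:
        return True
    o1, o2 = obs.alleles
    if o2 is MISSING:  # one-sided call: the seen allele must be present
        return o1 in (x, y)
    true = tuple(sorted((x, y), key=_allele_sort_key))
    if o2 is NULL:
        if o1 is NULL:
            return true == (NULL, NULL)
        return true == (o1, NULL)
    if o1 == o2:  # apparent homozygote: true homozygote or hidden null
        return true == (o1, o1) or true == (o1, NULL)
    return true == (o1, o2)


def validate_mendelian(family: Family) -> list:
    """Report offspring genotypes impossible given the parents.

    Null alleles are treated as inheritable: a parent's apparent homozygote
    may hide a null, and an offspring's apparent homozygote may have received
    one.  Missing calls are always compatible.
    """
    violations = []
    loci = set(family.father.genotypes) | set(family.mother.genotypes)
    for off in family.offspring:
        loci_off = loci | set(off.genotypes)
        for locus in sorted(loci_off):
            obs = off.genotype(locus)
            if obs.is_untyped:
                continue
            xs = _transmissible(family.father.genotype(locus))
            ys = _transmissible(family.mother.genotype(locus))
            if xs is None:
                xs = list(dict.fromkeys([a for a in obs.alleles if a is not MISSING])) or [NULL]
                xs.append(NULL)
            if ys is None:
                ys = list(dict.fromkeys([a for a in obs.alleles if a is not MISSING])) or [NULL]
                ys.append(NULL)
            if not any(_offspring_compatible(obs, x, y) for x in xs for y in ys):
                violations.append(
                    MendelViolation(
                        family.father.id,
                        off.id,
                        locus,
                        f"offspring {obs!r} incompatible with parents "
                        f"{family.father.genotype(locus)!r} x {family.mother.genotype(locus)!r}",
                    )
                )
    return violations


# ---------------------------------------------------------------------------
# Genotype table I/O

FIXED_COLUMNS = ["id", "family", "role", "sex", "species", "population"]


class GenotypeTableError(ValueError):
    pass


def _parse_allele(token: str, lineno: int):
    token = token.strip()
    if token == NULL_TOKEN:
        return NULL
    if token == MISSING_TOKEN or token == "":
        return MISSING
    try:
        return int(token)
    except ValueError:
        raise GenotypeTableError(
            f"line {lineno}: allele size {token!r} is not an integer"
        ) from None


def read_genotype_table(path) -> Dataset:
    """Read the genotype CSV dialect into a :class:`Dataset`.

    Header: ``id,family,role,sex,species,population`` followed by two columns
    per locus named ``<locus>.a1`` and ``<locus>.a2``.  ``family`` is empty
    for unrelated adults.  ``*`` is a null allele, ``NA`` a missing call.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise GenotypeTableError("line 1: empty file")
    header = [c.strip() for c in lines[0].split(",")]
    if header[: len(FIXED_COLUMNS)] != FIXED_COLUMNS:
        raise GenotypeTableError(
            f"line 1: header must start with {','.join(FIXED_COLUMNS)}"
        )
    locus_cols = header[len(FIXED_COLUMNS):]
    if len(locus_cols) % 2 != 0:
        raise GenotypeTableError("line 1: odd number of allele columns")
    loci = []
    for i in range(0, len(locus_cols), 2):
        c1, c2 = locus_cols[i], locus_cols[i + 1]
        if not c1.endswith(".a1") or not c2.endswith(".a2") or c1[:-3] != c2[:-3]:
            raise GenotypeTableError(
                f"line 1: locus columns must come in <locus>.a1,<locus>.a2 pairs "
                f"(got {c1!r},{c2!r})"
            )
        loci.append(LocusDef(c1[:-3]))
    n_cols = len(header)

    seen_ids = set()
    fam_rows: dict = {}
    adults = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != n_cols:
            raise GenotypeTableError(
                f"line {lineno}: expected {n_cols} columns, got {len(cells)}"
            )
        ind_id, fam_id, role, sex, species, population = cells[:6]
        if ind_id in seen_ids:
            raise GenotypeTableError(f"line {lineno}: duplicate individual id {ind_id!r}")
        seen_ids.add(ind_id)
        if role not in ROLES:
            raise GenotypeTableError(f"line {lineno}: unknown role {role!r}")
        if sex not in SEXES:
            raise GenotypeTableError(f"line {lineno}: unknown sex {sex!r}")
        genotypes = {}
        for k, locus in enumerate(loci):
            a1 = _parse_allele(cells[6 + 2 * k], lineno)
            a2 = _parse_allele(cells[7 + 2 * k], lineno)
            g = Genotype(a1, a2)
            if not g.is_untyped:
                genotypes[locus.name] = g
        try:
            ind = Individual(ind_id, sex, role, species, population, genotypes)
        except ValueError as e:
            raise GenotypeTableError(f"line {lineno}: {e}") from None
        if role == "adult":
            if fam_id:
                raise GenotypeTableError(
                    f"line {lineno}: unrelated adult {ind_id!r} must have empty family"
                )
            adults.append(ind)
        else:
            if not fam_id:
                raise GenotypeTableError(
                    f"line {lineno}: {role} {ind_id!r} needs a family id"
                )
            fam_rows.setdefault(fam_id, {"father": None, "mother": None, "offspring": []})
            slot = fam_rows[fam_id]
            if role in ("father", "mother"):
                if slot[role] is not None:
                    raise GenotypeTableError(
                        f"line {lineno}: family {fam_id!r} has two {role}s"
                    )
                slot[role] = ind
            else:
                slot["offspring"].append(ind)

    families = []
    for fam_id, slot in fam_rows.items():
        if slot["father"] is None or slot["mother"] is None:
            raise GenotypeTableError(f"family {fam_id!r} lacks a father or mother")
        try:
            families.append(Family(slot["father"], slot["mother"], slot["offspring"]))
        except ValueError as e:
            raise GenotypeTableError(f"family {fam_id!r}: {e}") from None
    return Dataset(loci=loci, families=families, adults=adults)


def write_genotype_table(dataset: Dataset, path=None) -> str:
    """Write a Dataset in the canonical genotype CSV form; returns the text."""
    cols = list(FIXED_COLUMNS)
    for l in dataset.loci:
        cols += [f"{l.name}.a1", f"{l.name}.a2"]
    out = [",".join(cols)]

    def row(ind: Individual, fam_id: str):
        cells = [ind.id, fam_id, ind.role, ind.sex, ind.species, ind.population]
        for l in dataset.loci:
            g = ind.genotype(l.name)
            cells += [format_allele(g.allele1), format_allele(g.allele2)]
        return ",".join(cells)

    for i, fam in enumerate(dataset.families, start=1):
        fam_id = f"F{i}"
        out.append(row(fam.father, fam_id))
        out.append(row(fam.mother, fam_id))
        for off in fam.offspring:
            out.append(row(off, fam_id))
    for ad in dataset.adults:
        out.append(row(ad, ""))
    text = "\n".join(out) + "\n"
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Tip labels, trees, alignments


@dataclass(frozen=True)
class TipLabel:
    species: str
    gametolog: str
    individual: str
    clone: str | None = None

    def __post_init__(self):
        if self.gametolog not in GAMETOLOGS:
            raise ValueError(
                f"gametolog must be one of {GAMETOLOGS}, got {self.gametolog!r}"
            )

    def __str__(self) -> str:
        parts = [self.species, self.gametolog, self.individual]
        if self.clone is not None:
            parts.append(self.clone)
        return "|".join(parts)

    @classmethod
    def parse(cls, text: str) -> "TipLabel":
        parts = text.split("|")
        if len(parts) not in (3, 4):
            raise ValueError(
                f"tip label {text!r} must be species|gametolog|individual[|clone]"
            )
        try:
            return cls(*parts)
        except ValueError as e:
            raise ValueError(f"tip label {text!r}: {e}") from None


class LabeledTree:
    """Branch-length tree whose tips carry :class:`TipLabel` annotations.

    Thin wrapper around a :class:`dendropy.Tree`; branch lengths are in
    whatever unit the producer used (substitutions/site for inferred trees,
    generations for simulated genealogies).  Per-edge bootstrap supports, if
    any, live on internal node labels.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.negative_lengths_clamped = False
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for lf in tree.leaf_node_iter():
            TipLabel.parse(lf.taxon.label)  # raises naming the tip

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            real_value_format_specifier=".10g",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    # -- queries -------------------------------------------------------------

    @property
    def tip_labels(self) -> list:
        return [TipLabel.parse(lf.taxon.label) for lf in self.tree.leaf_node_iter()]

    @property
    def tip_names(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def bipartitions(self) -> set:
        """Non-trivial splits as canonical frozensets of tip-name strings.

        Each internal edge splits the tips in two; the side not containing
        the lexicographically smallest tip is the canonical representative,
        so the set is invariant to rooting.
        """
        all_tips = frozenset(self.tip_names)
        anchor = min(all_tips)
        splits = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if anchor in side:
                side = all_tips - side
            if 1 < len(side) < len(all_tips) - 1:
                splits.add(side)
        return splits

    def is_split(self, tipset) -> bool:
        """Does ``tipset`` form one side of an edge of the unrooted tree?

        This is the unrooted notion of monophyly: a set of k tips is
        "monophyletic" iff some edge separates exactly those tips from the
        rest.  Trivial sets (singletons, all tips, all-but-one) always pass.
        """
        tipset = frozenset(str(t) for t in tipset)
        all_tips = frozenset(self.tip_names)
        if not tipset <= all_tips:
            raise ValueError("tipset contains labels not in the tree")
        if len(tipset) <= 1 or len(all_tips) - len(tipset) <= 1:
            return True
        anchor = min(all_tips)
        canonical = tipset if anchor not in tipset else all_tips - tipset
        return canonical in self.bipartitions()


def read_newick(path) -> LabeledTree:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return LabeledTree.from_newick(text)


def write_newick(tree: LabeledTree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


ALIGNMENT_ALPHABET = set("ACGT-")


@dataclass
class Alignment:
    """Aligned sequences over {A,C,G,T,-} keyed by :class:`TipLabel`."""

    records: list  # list of (TipLabel, str)

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment needs at least one record")
        L = len(self.records[0][1])
        for label, seq in self.records:
            if len(seq) != L:
                raise ValueError(
                    f"ragged alignment: {label} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise ValueError(f"sequence {label} has characters outside ACGT-: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.records]


def read_fasta(path) -> Alignment:
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "r", encoding="utf-8")
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            label = TipLabel.parse(rec.id)
            records.append((label, str(rec.seq).upper()))
    finally:
        if handle is not path:
            handle.close()
    return Alignment(records)


def write_fasta(alignment: Alignment, path=None) -> str:
    recs = [
        SeqRecord(Seq(seq), id=str(label), description="")
        for label, seq in alignment.records
    ]
    buf = _io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=80)
    writer.write_file(recs)
    text = buf.getvalue()
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text
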