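"""Aligned-sequence containers, haplotype collapsing and site classification.

The central objects are :class:`Alignment` (an equal-length matrix of
sequences over ``{A, C, G, T, -, N}``), :class:`PopulationMap` (individual ->
population -> region labels) and :class:`HaplotypeTable` (distinct sequences
with per-population counts).  All downstream statistics (diversity indices,
AMOVA, mismatch distributions, networks) are built from these.

Conventions
-----------
* ``N`` (and any IUPAC ambiguity code) is treated as missing data: excluded
  per-site when classifying variability and per-pair when counting
  differences (pairwise deletion).
* A site containing ``-`` is flagged as an indel site; it may still be
  variable, but it is excluded from transition/transversion counting.
  Indel-only variation is tallied separately from substitution variation.
* Haplotype identity is exact string equality after uppercase normalisation;
  sequences differing only at missing positions are *not* merged.
* Site coordinates are 1-based in all user-facing outputs.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "PopulationMap",
    "HaplotypeTable",
    "SiteSummary",
    "AlignmentError",
    "read_fasta_alignment",
    "read_population_table",
    "write_fasta",
    "concatenate",
    "collapse_haplotypes",
    "classify_sites",
    "pairwise_differences",
]

VALID_BASES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
GAP = "-"
MISSING = "N"


class AlignmentError(ValueError):
    """Raised for ragged input, duplicate ids or mismatched label tables."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences with unique ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if self.seqs:
            k = len(self.seqs[0])
            bad = [i for i, s in zip(self.ids, self.seqs) if len(s) != k]
            if bad:
                raise AlignmentError(f"ragged alignment; offending ids: {bad}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for name, seq in pairs:
            ids.append(str(name))
            seqs.append(str(seq).upper())
        return cls(tuple(ids), tuple(seqs))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """Return the alignment as an ``(n, k)`` array of single characters."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.length)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {i: s for i, s in zip(self.ids, self.seqs)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise AlignmentError(f"unknown sequence ids: {missing}")
        return Alignment(tuple(ids), tuple(index[i] for i in ids))

    def take_sites(self, sites: Sequence[int]) -> "Alignment":
        """Column subset/resample (0-based site indices); used for bootstrap."""
        mat = self.matrix()[:, list(sites)]
        seqs = tuple(row.tobytes().decode("ascii") for row in mat)
        return Alignment(self.ids, seqs)


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of individuals to populations and populations to regions."""

    population: Mapping[str, str]
    region: Mapping[str, str] = field(default_factory=dict)
    coordinates: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def region_of_population(self, pop: str) -> str:
        for ind, p in self.population.items():
            if p == pop and ind in self.region:
                return self.region[ind]
        raise KeyError(f"no region recorded for population {pop!r}")

    def populations_by_region(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop in self.populations():
            out.setdefault(self.region_of_population(pop), []).append(pop)
        return out

    def labels_for(self, ids: Sequence[str]) -> list[str]:
        unmapped = [i for i in ids if i not in self.population]
        if unmapped:
            raise AlignmentError(
                f"individuals missing from population table: {unmapped}"
            )
        return [self.population[i] for i in ids]

    def members(self, pop: str) -> list[str]:
        return [i for i, p in self.population.items() if p == pop]


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with per-population frequency counts.

    ``counts`` has one row per haplotype (in first-occurrence order) and one
    column per population; ``counts.values.sum()`` equals the number of
    individuals collapsed.
    """

    sequences: tuple[str, ...]
    counts: pd.DataFrame
    members: tuple[tuple[str, ...], ...] = ()

    @property
    def h(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def total_counts(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def labels(self) -> list[str]:
        return list(self.counts.index)

    def to_alignment(self) -> Alignment:
        return Alignment(tuple(self.counts.index), self.sequences)

    def expand(self) -> list[str]:
        """Reconstruct the multiset of input sequences (order by haplotype)."""
        out: list[str] = []
        totals = self.total_counts()
        for seq, c in zip(self.sequences, totals):
            out.extend([seq] * int(c))
        return out


@dataclass(frozen=True)
class SiteSummary:
    """Per-site classification of an alignment."""

    table: pd.DataFrame  # columns: site, variable, parsimony_informative, substitution_type, indel

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def n_variable(self) -> int:
        """Substitution-variable sites (indel-only variation not counted)."""
        t = self.table
        return int((t["variable"] & (t["substitution_type"] != "none")).sum())

    @property
    def n_indel_variable(self) -> int:
        t = self.table
        return int((t["variable"] & (t["substitution_type"] == "none")).sum())

    @property
    def n_parsimony_informative(self) -> int:
        return int(self.table["parsimony_informative"].sum())

    @property
    def n_transitions(self) -> int:
        return int((self.table["substitution_type"] == "transition").sum())

    @property
    def n_transversions(self) -> int:
        return int((self.table["substitution_type"] == "transversion").sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_population_table(path) -> PopulationMap:
    """Read a 2/3(+2)-column delimited table: id, population[, region[, x, y]]."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise AlignmentError("population table needs at least id + population")
    ids = df[cols[0]].astype(str)
    if ids.duplicated().any():
        raise AlignmentError(
            f"duplicate individuals in population table: "
            f"{sorted(ids[ids.duplicated()].unique())}"
        )
    pop = dict(zip(ids, df[cols[1]].astype(str)))
    region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    if len(cols) >= 3:
        region = dict(zip(ids, df[cols[2]].astype(str)))
    if len(cols) >= 5:
        coords = {
            i: (float(x), float(y))
            for i, x, y in zip(ids, df[cols[3]], df[cols[4]])
        }
    return PopulationMap(pop, region, coords)


def read_fasta_alignment(path, population_table=None) -> tuple[Alignment, PopulationMap | None]:
    """Read an aligned FASTA; optionally attach and validate a population map.

    Sequences are uppercased.  Errors on ragged records or ids absent from
    the population table.
    """
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise AlignmentError(f"no FASTA records in {path}")
    aln = Alignment.from_pairs(pairs)
    pm = None
    if population_table is not None:
        pm = (
            population_table
            if isinstance(population_table, PopulationMap)
            else read_population_table(population_table)
        )
        pm.labels_for(aln.ids)  # raises with the offending ids
    return aln, pm


def write_fasta(aln: Alignment, path, descriptions: Mapping[str, str] | None = None) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description=(descriptions or {}).get(name, ""),
        )
        for name, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_haplotype_fasta(ht: HaplotypeTable, path) -> None:
    """Haplotype FASTA with per-population frequencies in the description."""
    desc = {}
    for label, row in ht.counts.iterrows():
        parts = [f"{p}:{int(c)}" for p, c in row.items() if c > 0]
        desc[label] = f"n={int(row.sum())} " + " ".join(parts)
    write_fasta(ht.to_alignment(), path, descriptions=desc)


def concatenate(a: Alignment, b: Alignment) -> Alignment:
    """5'-``a``-``b``-3' concatenation over an identical id set."""
    if set(a.ids) != set(b.ids):
        only_a = sorted(set(a.ids) - set(b.ids))
        only_b = sorted(set(b.ids) - set(a.ids))
        raise AlignmentError(
            f"id sets differ; only in first: {only_a}; only in second: {only_b}"
        )
    b_index = dict(zip(b.ids, b.seqs))
    return Alignment(a.ids, tuple(s + b_index[i] for i, s in zip(a.ids, a.seqs)))


def collapse_haplotypes(aln: Alignment, pm: PopulationMap | None = None) -> HaplotypeTable:
    """Merge identical sequences into haplotypes numbered in first-occurrence order."""
    if aln.n == 0:
        raise AlignmentError("empty alignment")
    if pm is not None:
        pop_labels = pm.labels_for(aln.ids)
        pops = pm.populations()
        pops = [p for p in pops if p in set(pop_labels)]
    else:
        pop_labels = ["all"] * aln.n
        pops = ["all"]
    order: dict[str, int] = {}
    members: list[list[str]] = []
    counts: list[list[int]] = []
    pop_index = {p: j for j, p in enumerate(pops)}
    for name, seq, pop in zip(aln.ids, aln.seqs, pop_labels):
        if seq not in order:
            order[seq] = len(order)
            members.append([])
            counts.append([0] * len(pops))
        idx = order[seq]
        members[idx].append(name)
        counts[idx][pop_index[pop]] += 1
    labels = [f"Hap{i + 1:02d}" for i in range(len(order))]
    df = pd.DataFrame(counts, index=labels, columns=pops)
    return HaplotypeTable(
        tuple(order), df, tuple(tuple(m) for m in members)
    )


def _classify_site(column: np.ndarray) -> tuple[bool, bool, str, bool]:
    """Classify one alignment column.

    Returns (variable, parsimony_informative, substitution_type, indel).
    ``substitution_type`` in {"none", "transition", "transversion", "mixed"} —
    "none" for invariant or indel/missing-only variation.
    """
    chars = [c.decode("ascii") for c in column]
    indel = GAP in chars
    bases = [c for c in chars if c in VALID_BASES]
    states = sorted(set(bases))
    variable_subst = len(states) >= 2
    # indel-only variation: site varies because of gaps, bases themselves agree
    variable = variable_subst or (indel and len(set(chars)) >= 2)
    pi = False
    subst = "none"
    if variable_subst:
        from collections import Counter

        cnt = Counter(bases)
        pi = sum(1 for v in cnt.values() if v >= 2) >= 2
        if not indel:
            kinds = set()
            for x, y in itertools.combinations(states, 2):
                same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
                kinds.add("transition" if same_class else "transversion")
            subst = kinds.pop() if len(kinds) == 1 else "mixed"
    return variable, pi, subst, indel


def classify_sites(aln: Alignment) -> SiteSummary:
    """Per-site variability, parsimony information, ts/tv type and indel flag.

    Missing data (``N``) are excluded per site.  Gap-containing sites are
    flagged ``indel`` and excluded from ts/tv typing, matching the practice
    of reporting indel variation separately from substitutions.
    """
    mat = aln.matrix()
    rows = []
    for j in range(aln.length):
        variable, pi, subst, indel = _classify_site(mat[:, j])
        rows.append(
            {
                "site": j + 1,
                "variable": variable,
                "parsimony_informative": pi,
                "substitution_type": subst,
                "indel": indel,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["site", "variable", "parsimony_informative", "substitution_type", "indel"],
    )
    return SiteSummary(table)


def pairwise_differences(aln: Alignment, return_compared: bool = False):
    """Pairwise difference counts under pairwise deletion of gap/N positions.

    Returns an ``(n, n)`` integer matrix; with ``return_compared=True`` also
    returns the matrix of per-pair compared-site counts.  Note the triangle
    inequality can fail for counts under pairwise deletion; no repair is
    attempted.
    """
    mat = aln.matrix()
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    n = aln.n
    diffs = np.zeros((n, n), dtype=np.int64)
    compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = (mat[i] != mat[i + 1 :]) & both
        diffs[i, i + 1 :] = d.sum(axis=1)
        compared[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    compared += compared.T
    np.fill_diagonal(compared, int(valid.sum(axis=1).min()) if n else 0)
    if return_compared:
        return diffs, compared
    return diffs
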