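"""Diversity indices, Kimura two-parameter distances and NJ trees.

Indices follow the standard estimators: Nei's haplotype diversity with the
``n/(n-1)`` small-sample correction, mean pairwise differences ``K`` over
unordered pairs, and per-site nucleotide diversity ``pi`` with a pairwise-
deletion denominator averaged over pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import (
    Alignment,
    HaplotypeTable,
    PopulationMap,
    classify_sites,
    collapse_haplotypes,
    pairwise_differences,
)

__all__ = [
    "DiversityReport",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_report",
    "k2p",
    "k2p_matrix",
    "group_k2p",
    "Tree",
    "neighbor_joining",
    "build_nj_tree",
    "bootstrap_support",
    "SaturationError",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """A statistic was requested for a sample too small to define it."""


class SaturationError(ValueError):
    """K2P log argument non-positive: sequences too divergent for the model."""


@dataclass(frozen=True)
class DiversityReport:
    n: int
    S: int
    h: int
    Hd: float
    pi: float
    K: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "S": self.S,
            "h": self.h,
            "Hd": self.Hd,
            "pi": self.pi,
            "K": self.K,
        }


def haplotype_diversity(ht: HaplotypeTable | np.ndarray) -> float:
    """Nei's Hd = n/(n-1) * (1 - sum p_i^2) from haplotype counts."""
    counts = (
        ht.total_counts() if isinstance(ht, HaplotypeTable) else np.asarray(ht, dtype=float)
    )
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(aln: Alignment) -> tuple[float, float]:
    """Return (pi, K): per-site nucleotide diversity and mean pairwise differences.

    K averages difference counts over all C(n,2) unordered pairs; pi divides
    by the mean number of sites compared per pair (pairwise deletion).
    """
    if aln.n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    diffs, compared = pairwise_differences(aln, return_compared=True)
    iu = np.triu_indices(aln.n, k=1)
    K = float(diffs[iu].mean())
    eff_len = float(compared[iu].mean())
    if eff_len == 0:
        raise UndefinedStatisticError("no comparable sites after pairwise deletion")
    return K / eff_len, K


def diversity_report(aln: Alignment, pm: PopulationMap | None = None) -> DiversityReport:
    """n, S, h, Hd, pi, K for one sample (restrict the alignment beforehand
    for per-population reports)."""
    ht = collapse_haplotypes(aln, pm)
    summary = classify_sites(aln)
    pi, K = nucleotide_diversity(aln)
    return DiversityReport(
        n=aln.n,
        S=summary.n_variable,
        h=ht.h,
        Hd=haplotype_diversity(ht),
        pi=pi,
        K=K,
    )


def per_population_report(aln: Alignment, pm: PopulationMap) -> pd.DataFrame:
    rows = {}
    for pop in pm.populations():
        ids = [i for i in aln.ids if pm.population[i] == pop]
        if len(ids) < 2:
            continue
        rows[pop] = diversity_report(aln.subset(ids)).as_dict()
    rows["all"] = diversity_report(aln, pm).as_dict()
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Kimura two-parameter distances
# ---------------------------------------------------------------------------

_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")


def _p_q(a: str, b: str) -> tuple[float, float, int]:
    """Transition/transversion proportions over jointly valid sites."""
    ts = tv = valid = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        if (x in "AG") == (y in "AG"):
            ts += 1
        else:
            tv += 1
    return (ts / valid if valid else 0.0, tv / valid if valid else 0.0, valid)


def k2p(a: str, b: str) -> float:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    P, Q, valid = _p_q(a, b)
    if valid == 0:
        raise UndefinedStatisticError("no comparable sites")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(aln: Alignment) -> pd.DataFrame:
    """Symmetric matrix of pairwise K2P distances."""
    n = aln.n
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = k2p(aln.seqs[i], aln.seqs[j])
    return pd.DataFrame(out, index=aln.ids, columns=aln.ids)


def group_k2p(aln: Alignment, pm: PopulationMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean K2P within/between populations.

    Returns (raw, net): ``raw`` holds the mean pairwise distance (diagonal =
    within-population mean); ``net`` the between-group distance corrected for
    within-group diversity, dA = dXY - (dX + dY)/2.
    """
    dm = k2p_matrix(aln).to_numpy()
    labels = np.array(pm.labels_for(aln.ids))
    pops = [p for p in pm.populations() if p in set(labels)]
    raw = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations_with_replacement(pops, 2):
        ia = np.flatnonzero(labels == a)
        ib = np.flatnonzero(labels == b)
        if a == b:
            if len(ia) < 2:
                raw.loc[a, a] = np.nan
                continue
            iu = np.triu_indices(len(ia), k=1)
            raw.loc[a, a] = dm[np.ix_(ia, ia)][iu].mean()
        else:
            raw.loc[a, b] = raw.loc[b, a] = dm[np.ix_(ia, ib)].mean()
    net = raw.copy()
    for a, b in itertools.combinations(pops, 2):
        net.loc[a, b] = net.loc[b, a] = raw.loc[a, b] - (
            raw.loc[a, a] + raw.loc[b, b]
        ) / 2.0
    np.fill_diagonal(net.values, 0.0)
    return raw, net


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Minimal rooted-topology container for NJ output.

    ``children`` maps a node id to [(child_id, branch_length), ...]; leaves
    carry taxon labels.  NJ trees are unrooted; the trifurcating "root" is a
    representation artifact.
    """

    children: dict[int, list[tuple[int, float]]]
    labels: dict[int, str]
    root: int
    negative_clamped: bool = False

    def leaves(self, node: int | None = None) -> list[str]:
        node = self.root if node is None else node
        if node in self.labels:
            return [self.labels[node]]
        out: list[str] = []
        for child, _ in self.children.get(node, []):
            out.extend(self.leaves(child))
        return out

    def newick(self) -> str:
        def fmt(node: int) -> str:
            if node in self.labels:
                return self.labels[node]
            inner = ",".join(
                f"{fmt(c)}:{bl:.6f}" for c, bl in self.children[node]
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the smaller/lexicographic side."""
        all_taxa = frozenset(self.leaves())
        splits: set[frozenset[str]] = set()
        for node in self.children:
            for child, _ in self.children[node]:
                if child in self.labels:
                    continue
                side = frozenset(self.leaves(child))
                other = all_taxa - side
                if len(side) < 2 or len(other) < 2:
                    continue
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits


def neighbor_joining(dist: pd.DataFrame) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label, label) pair.  Negative branch lengths are clamped to zero and the
    tree flagged.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = {(a, b): float(dist.loc[a, b]) for a in labels for b in labels}
    node_of = {lab: i for i, lab in enumerate(labels)}
    tree_labels = {i: lab for lab, i in node_of.items()}
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = len(labels)
    active = list(labels)
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * D[(a, b)] - R[a] - R[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, f, g = best
        d_fg = D[(f, g)]
        bl_f = clamp(0.5 * d_fg + (R[f] - R[g]) / (2 * (r - 2)))
        bl_g = clamp(d_fg - (0.5 * d_fg + (R[f] - R[g]) / (2 * (r - 2))))
        new = f"__internal{next_id}"
        children[next_id] = [(node_of[f], bl_f), (node_of[g], bl_g)]
        node_of[new] = next_id
        next_id += 1
        for a in active:
            if a in (f, g):
                continue
            d = 0.5 * (D[(f, a)] + D[(g, a)] - d_fg)
            D[(new, a)] = D[(a, new)] = d
        D[(new, new)] = 0.0
        active = [a for a in active if a not in (f, g)] + [new]

    a, b, c = sorted(active, key=lambda x: (x.startswith("__"), x))
    d_ab, d_ac, d_bc = D[(a, b)], D[(a, c)], D[(b, c)]
    bl_a = clamp(0.5 * (d_ab + d_ac - d_bc))
    bl_b = clamp(0.5 * (d_ab + d_bc - d_ac))
    bl_c = clamp(0.5 * (d_ac + d_bc - d_ab))
    root = next_id
    children[root] = [
        (node_of[a], bl_a),
        (node_of[b], bl_b),
        (node_of[c], bl_c),
    ]
    return Tree(children=children, labels=tree_labels, root=root, negative_clamped=clamped)


def build_nj_tree(dist: pd.DataFrame, outgroup: str | None = None) -> Tree:
    """NJ tree from a distance matrix, optionally rooted on an outgroup edge."""
    tree = neighbor_joining(dist)
    if outgroup is None:
        return tree
    if outgroup not in set(tree.labels.values()):
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    # root on the midpoint of the outgroup's pendant edge
    og_node = next(i for i, lab in tree.labels.items() if lab == outgroup)
    parent, bl = next(
        (p, bl)
        for p, kids in tree.children.items()
        for c, bl in kids
        if c == og_node
    )
    # re-hang: new root with outgroup on one side, rest re-oriented below
    adj: dict[int, list[tuple[int, float]]] = {}
    for p, kids in tree.children.items():
        for c, b in kids:
            adj.setdefault(p, []).append((c, b))
            adj.setdefault(c, []).append((p, b))
    new_root = max(tree.children) + 1
    children: dict[int, list[tuple[int, float]]] = {
        new_root: [(og_node, bl / 2)]
    }

    def orient(node: int, avoid: int) -> None:
        for nb, b in adj.get(node, []):
            if nb == avoid:
                continue
            children.setdefault(node, []).append((nb, b))
            orient(nb, node)

    children[new_root].append((parent, bl / 2))
    orient(parent, og_node)
    return Tree(
        children=children,
        labels=tree.labels,
        root=new_root,
        negative_clamped=tree.negative_clamped,
    )


def bootstrap_support(
    aln: Alignment,
    B: int = 1000,
    seed: int | None = None,
    tree: Tree | None = None,
    dist_fn=k2p_matrix,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for each bipartition of ``tree``.

    ``tree`` defaults to NJ on ``dist_fn(aln)``; support is the fraction of
    replicates whose NJ tree contains the split.
    """
    if B < 1:
        raise ValueError("B >= 1 required")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = neighbor_joining(dist_fn(aln))
    target = tree.bipartitions()
    hits = {split: 0 for split in target}
    for _ in range(B):
        sites = rng.integers(0, aln.length, size=aln.length)
        rep = aln.take_sites(sites)
        try:
            rep_tree = neighbor_joining(dist_fn(rep))
        except SaturationError:
            continue
        found = rep_tree.bipartitions()
        for split in target:
            if split in found:
                hits[split] += 1
    return {split: hits[split] / B for split in target}
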