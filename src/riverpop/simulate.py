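"""Synthetic-data generators: coalescent sequence samples and tetraploid bands.

The coalescent engine works in *mutational time units*: the pairwise
coalescence rate in a deme of scaled size ``theta`` is ``1/theta`` and each
lineage mutates at rate 1/2 per unit time.  Under this scaling a constant-
size sample has expected pairwise difference ``theta``, expected segregating
sites ``theta * sum(1/i)``, and a size change at time ``tau`` produces a
mismatch mode near ``tau`` — i.e. ``tau`` here is directly comparable to the
sudden-expansion parameter estimated from mismatch distributions.

The engine is implemented directly (exponential waiting times, piecewise
rescaling) so that the goodness-of-fit parametric bootstrap is fully
self-contained and byte-reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import Alignment, PopulationMap

__all__ = [
    "DemographicScenario",
    "simulate_coalescent",
    "simulate_genealogy",
    "simulate_structured",
    "simulate_tetraploid_bands",
    "simulate_binary_hierarchy",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class DemographicScenario:
    """Sudden-expansion (or constant-size) sampling scenario.

    ``theta1`` is the current scaled size, ``theta0`` the size before time
    ``tau`` (set ``tau=0`` or ``theta0 == theta1`` for constant size).
    ``ts_tv`` is the transition/transversion *event* ratio used for
    finite-sites mutation placement.
    """

    n: int
    k: int = 1000
    theta0: float = 1.0
    theta1: float = 1.0
    tau: float = 0.0
    ts_tv: float = 10.0
    infinite_sites: bool = False
    seed: int | None = None


@dataclass
class Genealogy:
    """Binary coalescent tree: nodes 0..n-1 are leaves, root is 2n-2."""

    n: int
    parent: np.ndarray  # parent id per node (-1 for root)
    time: np.ndarray  # node times (leaves at 0)

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(2 * self.n - 1)
        for v in range(2 * self.n - 2):
            bl[v] = self.time[self.parent[v]] - self.time[v]
        return bl

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for v in range(2 * self.n - 2):
            out.setdefault(int(self.parent[v]), []).append(v)
        return out

    def leaves_below(self) -> dict[int, np.ndarray]:
        """Boolean leaf-membership mask per node."""
        children = self.children()
        masks = {v: np.zeros(self.n, dtype=bool) for v in range(2 * self.n - 1)}
        for v in range(self.n):
            masks[v][v] = True
        for v in range(self.n, 2 * self.n - 1):
            for c in children[v]:
                masks[v] |= masks[c]
        return masks


def _piecewise_exponential(rng, rate_recent, rate_old, t, boundary) -> float:
    """Next event time for a piecewise-constant rate (switch at ``boundary``)."""
    while True:
        rate = rate_recent if t < boundary else rate_old
        if rate <= 0:
            return math.inf
        w = rng.exponential(1.0 / rate)
        if t < boundary < t + w:
            t = boundary  # memoryless restart at the epoch boundary
            continue
        return t + w


def simulate_genealogy(
    n: int, theta0: float, theta1: float, tau: float, rng
) -> Genealogy:
    """Single-deme coalescent with a size change at time ``tau``."""
    # theta -> 0 means effectively instantaneous coalescence in that epoch
    theta0 = max(theta0, 1e-9)
    theta1 = max(theta1, 1e-9)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        j = len(active)
        pairs = j * (j - 1) / 2.0
        t = _piecewise_exponential(
            rng, pairs / theta1, pairs / theta0, t, tau
        )
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active.pop(i2)
        active.pop(i1)
        active.append(next_node)
        next_node += 1
    return Genealogy(n=n, parent=parent, time=time)


def _mutate_on_tree(
    gen: Genealogy,
    k: int,
    ts_tv: float,
    infinite_sites: bool,
    rng,
) -> list[str]:
    """Drop Poisson(branch_length / 2) mutations per branch; return leaf seqs."""
    n = gen.n
    bl = gen.branch_lengths()
    n_mut = rng.poisson(bl / 2.0)
    total = int(n_mut[: 2 * n - 2].sum())
    if infinite_sites:
        if total > k:
            raise ValueError(
                f"{total} mutations exceed {k} sites under infinite sites"
            )
        mut_sites = rng.choice(k, size=total, replace=False)
    else:
        mut_sites = rng.integers(0, k, size=total)
    # assign site indices to branches in node order
    site_of_branch: dict[int, np.ndarray] = {}
    pos = 0
    for v in range(2 * n - 2):
        m = int(n_mut[v])
        site_of_branch[v] = mut_sites[pos : pos + m]
        pos += m
    ancestral = rng.choice(list("ACGT"), size=k)
    p_ts = ts_tv / (ts_tv + 1.0)
    children = gen.children()
    seqs: dict[int, np.ndarray] = {}
    root = 2 * n - 2
    stack = [(root, ancestral)]
    while stack:
        node, seq = stack.pop()
        if node != root:
            seq = seq.copy()
            for site in site_of_branch[node]:
                base = seq[site]
                if rng.random() < p_ts:
                    seq[site] = _TRANSITION[base]
                else:
                    seq[site] = _TRANSVERSIONS[base][int(rng.integers(2))]
        if node < n:
            seqs[node] = seq
        else:
            for c in sorted(children[node]):
                stack.append((c, seq))
    return ["".join(seqs[i]) for i in range(n)]


def simulate_coalescent(scn: DemographicScenario) -> tuple[Alignment, PopulationMap]:
    """Sample one panmictic alignment under ``scn`` (seed mandatory for pipelines)."""
    rng = np.random.default_rng(scn.seed)
    gen = simulate_genealogy(scn.n, scn.theta0, scn.theta1, scn.tau, rng)
    seqs = _mutate_on_tree(gen, scn.k, scn.ts_tv, scn.infinite_sites, rng)
    ids = tuple(f"ind{i + 1:03d}" for i in range(scn.n))
    aln = Alignment(ids, tuple(seqs))
    pm = PopulationMap(
        {i: "pop1" for i in ids}, {i: "west" for i in ids}
    )
    return aln, pm


def simulate_pair_differences(
    n: int, theta0: float, theta1: float, tau: float, rng
) -> np.ndarray:
    """Pairwise difference matrix under infinite sites, skipping sequence
    materialisation (fast path for parametric bootstraps)."""
    gen = simulate_genealogy(n, theta0, theta1, tau, rng)
    bl = gen.branch_lengths()
    n_mut = rng.poisson(bl / 2.0)
    masks = gen.leaves_below()
    diffs = np.zeros((n, n), dtype=np.int64)
    for v in range(2 * n - 2):
        m = int(n_mut[v])
        if m == 0:
            continue
        carrier = masks[v]
        out = ~carrier
        diffs[np.ix_(carrier, out)] += m
    diffs += diffs.T
    return diffs


def simulate_haplotype_counts(
    n: int, theta0: float, theta1: float, tau: float, rng
) -> tuple[int, float]:
    """(number of distinct haplotypes, mean pairwise differences) under
    infinite sites — sufficient statistics for Fu's Fs null simulations."""
    gen = simulate_genealogy(n, theta0, theta1, tau, rng)
    bl = gen.branch_lengths()
    n_mut = rng.poisson(bl / 2.0)
    masks = gen.leaves_below()
    profiles: list[tuple[int, ...]] = [() for _ in range(n)]
    diffs_total = 0.0
    for v in range(2 * n - 2):
        m = int(n_mut[v])
        if m == 0:
            continue
        carrier = masks[v]
        c = int(carrier.sum())
        diffs_total += m * c * (n - c)
        for leaf in np.flatnonzero(carrier):
            profiles[leaf] = profiles[leaf] + (v, m)
    h = len(set(profiles))
    K = diffs_total / (n * (n - 1) / 2.0)
    return h, K


def simulate_structured(
    n_per_pop: dict[str, int],
    region_of: dict[str, str],
    theta: float = 5.0,
    split_depth: float = 50.0,
    pop_depth: float = 2.0,
    migration: float = 0.0,
    k: int = 1000,
    ts_tv: float = 10.0,
    seed: int | None = None,
) -> tuple[Alignment, PopulationMap, pd.DataFrame]:
    """Two-level structured sample: populations merge into regional pools at
    ``pop_depth`` and regions merge at ``split_depth`` (mutational units).

    Before ``pop_depth`` lineages may migrate between populations of the same
    region at rate ``migration``/2 per lineage.  Also returns a synthetic
    matrix of along-river geographic distances (km) between populations.
    """
    if len(n_per_pop) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    pops = list(n_per_pop)
    regions = sorted(set(region_of[p] for p in pops))
    n = sum(n_per_pop.values())
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    # lineage state: (node_id, deme); demes switch identity at epoch bounds
    lineages: list[tuple[int, str]] = []
    idx = 0
    ids, pop_of_ind = [], {}
    for p in pops:
        for _ in range(n_per_pop[p]):
            name = f"{p}_{idx + 1:03d}"
            ids.append(name)
            pop_of_ind[name] = p
            lineages.append((idx, p))
            idx += 1
    t = 0.0
    next_node = n
    epochs = sorted({pop_depth, split_depth})

    def deme_at(pop: str, now: float) -> str:
        if now >= split_depth:
            return "__all__"
        if now >= pop_depth:
            return region_of[pop]
        return pop

    # lineages carry their *population of origin*; effective deme derived from t
    lin = [(node, pop) for node, pop in lineages]
    while len(lin) > 1:
        demes: dict[str, list[int]] = {}
        for i, (_, pop) in enumerate(lin):
            demes.setdefault(deme_at(pop, t), []).append(i)
        coal_rate = sum(
            len(members) * (len(members) - 1) / 2.0 / theta
            for members in demes.values()
        )
        mig_rate = 0.0
        if migration > 0 and t < pop_depth:
            for i, (_, pop) in enumerate(lin):
                same_region = [
                    q for q in pops if region_of[q] == region_of[pop] and q != pop
                ]
                if same_region:
                    mig_rate += migration / 2.0
        total = coal_rate + mig_rate
        next_boundary = next((e for e in epochs if e > t), math.inf)
        if total <= 0:
            t = next_boundary
            continue
        w = rng.exponential(1.0 / total)
        if t + w > next_boundary:
            t = next_boundary
            continue
        t += w
        if rng.random() < coal_rate / total:
            # choose a deme weighted by its pair count, then a random pair
            weights = np.array(
                [
                    len(members) * (len(members) - 1) / 2.0
                    for members in demes.values()
                ]
            )
            which = rng.choice(len(weights), p=weights / weights.sum())
            members = list(demes.values())[which]
            i1, i2 = sorted(rng.choice(len(members), size=2, replace=False))
            a, b = members[i1], members[i2]
            node_a, pop_a = lin[a]
            node_b, _ = lin[b]
            parent[node_a] = parent[node_b] = next_node
            time[next_node] = t
            for j in sorted((a, b), reverse=True):
                lin.pop(j)
            lin.append((next_node, pop_a))
            next_node += 1
        else:
            movable = [
                i
                for i, (_, pop) in enumerate(lin)
                if any(region_of[q] == region_of[pop] and q != pop for q in pops)
            ]
            i = movable[int(rng.integers(len(movable)))]
            node, pop = lin[i]
            targets = sorted(
                q for q in pops if region_of[q] == region_of[pop] and q != pop
            )
            lin[i] = (node, targets[int(rng.integers(len(targets)))])
    gen = Genealogy(n=n, parent=parent, time=time)
    seqs = _mutate_on_tree(gen, k, ts_tv, False, rng)
    aln = Alignment(tuple(ids), tuple(seqs))
    pm = PopulationMap(
        pop_of_ind, {i: region_of[pop_of_ind[i]] for i in ids}
    )
    # synthetic along-river distances: populations spaced 120 km within a
    # region, regions separated by a 900 km reach
    pos = {}
    for g_i, g in enumerate(regions):
        members = [p for p in pops if region_of[p] == g]
        for p_i, p in enumerate(members):
            pos[p] = g_i * 900.0 + p_i * 120.0
    geo = pd.DataFrame(
        [[abs(pos[a] - pos[b]) for b in pops] for a in pops],
        index=pops,
        columns=pops,
    )
    return aln, pm, geo


def simulate_tetraploid_bands(
    pop_allele_freqs: dict[str, dict[str, dict[int, float]]],
    n_per_pop: dict[str, int],
    seed: int | None = None,
):
    """Draw tetrasomic band phenotypes: 4 alleles per individual per locus,
    collapsed to the set of observed band sizes (1..4 bands).

    ``pop_allele_freqs[pop][locus]`` maps band size -> allele frequency
    (summing to 1 within each population x locus).
    """
    from .msat import BandPhenotypeMatrix

    rng = np.random.default_rng(seed)
    rows = []
    for pop, n_ind in n_per_pop.items():
        loci = pop_allele_freqs[pop]
        for i in range(n_ind):
            ind = f"{pop}_{i + 1:03d}"
            for locus, freqs in loci.items():
                bands = sorted(freqs)
                p = np.array([freqs[b] for b in bands], dtype=float)
                if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
                    raise ValueError(
                        f"allele frequencies for {pop}/{locus} do not sum to 1"
                    )
                draws = rng.choice(len(bands), size=4, p=p / p.sum())
                observed = sorted({bands[d] for d in draws})
                rows.append(
                    {
                        "individual": ind,
                        "population": pop,
                        "locus": locus,
                        "bands": tuple(observed),
                    }
                )
    df = pd.DataFrame(rows)
    return BandPhenotypeMatrix.from_long(df)


def simulate_binary_hierarchy(
    n_per_pop: dict[str, int],
    region_of: dict[str, str],
    n_cols: int = 200,
    fct: float = 0.09,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Binary presence/absence rows with a known among-region component.

    Per column, an overall frequency is drawn uniformly on (0.2, 0.8) and
    region frequencies from the Balding-Nichols beta with parameter ``fct``,
    so the expected among-region fixation index of the indicator variables is
    ``fct``.  Populations within a region share the regional frequency.
    Returns (matrix indexed by individual, population label per row).
    """
    rng = np.random.default_rng(seed)
    regions = sorted(set(region_of.values()))
    pbar = rng.uniform(0.2, 0.8, size=n_cols)
    a = pbar * (1.0 - fct) / fct
    b = (1.0 - pbar) * (1.0 - fct) / fct
    p_region = {g: rng.beta(a, b) for g in regions}
    data, index, pops = [], [], []
    for pop, n_ind in n_per_pop.items():
        p = p_region[region_of[pop]]
        for i in range(n_ind):
            data.append((rng.random(n_cols) < p).astype(np.int8))
            index.append(f"{pop}_{i + 1:03d}")
            pops.append(pop)
    df = pd.DataFrame(
        np.vstack(data),
        index=index,
        columns=[f"band{j + 1}" for j in range(n_cols)],
    )
    return df, pops
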