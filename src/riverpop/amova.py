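"""Hierarchical analysis of molecular variance (AMOVA) from distance matrices.

Variance components are obtained Excoffier-style: nested sums of squared
deviations computed directly from a matrix of squared pairwise distances,
with observed mean squares equated to their expectations using
unequal-sample-size coefficients.  Significance is assessed by permutation:

* ``Phi_ST`` (one- and two-level): individuals permuted among populations
  across the whole sample;
* ``Phi_SC``: individuals permuted among populations within groups;
* ``Phi_CT``: whole populations permuted among groups (exact enumeration when
  the arrangement space is smaller than the requested permutation count).

For sequence data the squared distance is the pairwise difference count; for
binary band data it is the squared Euclidean distance between 0/1 rows.
Negative variance components are retained in the fixation-index formulas but
flagged, and truncated at zero for the percentage display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AMOVAResult", "HierarchicalDesign", "amova", "pairwise_phi_st"]


@dataclass(frozen=True)
class HierarchicalDesign:
    """Population label per individual, and optional population -> group map."""

    populations: tuple[str, ...]
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        pops = sorted(set(self.populations))
        if len(pops) < 2:
            raise ValueError("AMOVA needs >= 2 populations")
        if self.group_of is not None:
            missing = [p for p in pops if p not in self.group_of]
            if missing:
                raise ValueError(f"populations without a group: {missing}")
            if len(set(self.group_of[p] for p in pops)) < 2:
                raise ValueError("two-level design needs >= 2 groups")


@dataclass
class AMOVAResult:
    df: dict[str, int]
    ssd: dict[str, float]
    sigma: dict[str, float]
    percent: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    negative_component: bool = False
    n_permutations: int = 0
    exact_ct: bool = False

    def table(self) -> pd.DataFrame:
        """Layout mirroring the conventional AMOVA report."""
        rows = []
        naming = {
            "among_groups": "Between regions",
            "among_populations": "Among populations",
            "among_populations_within_groups": "Among populations within regions",
            "within_populations": "Within populations",
        }
        for key in self.sigma:
            rows.append(
                {
                    "source": naming.get(key, key),
                    "df": self.df.get(key, np.nan),
                    "ssd": self.ssd.get(key, np.nan),
                    "variance_component": self.sigma[key],
                    "percent": self.percent[key],
                }
            )
        table = pd.DataFrame(rows)
        def stars(p: float) -> str:
            if not np.isfinite(p):
                return ""
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"

        phi_rows = pd.DataFrame(
            [
                {
                    "index": name,
                    "value": val,
                    "P": self.p_values.get(name, np.nan),
                    "signif": stars(self.p_values.get(name, np.nan)),
                }
                for name, val in self.phi.items()
            ]
        )
        return table, phi_rows


def _ssd_within(dsq: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) == 0:
        return 0.0
    sub = dsq[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _one_level_components(dsq: np.ndarray, pop_indices: list[np.ndarray]) -> tuple[float, float]:
    """(sigma_among, sigma_within) for a flat multi-population design."""
    N = sum(len(ix) for ix in pop_indices)
    P = len(pop_indices)
    all_idx = np.concatenate(pop_indices)
    ssd_total = _ssd_within(dsq, all_idx)
    ssd_wp = sum(_ssd_within(dsq, ix) for ix in pop_indices)
    ssd_ap = ssd_total - ssd_wp
    df_ap, df_wp = P - 1, N - P
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_c = (N - sum(len(ix) ** 2 for ix in pop_indices) / N) / df_ap
    sigma_c = ms_wp
    sigma_b = (ssd_ap / df_ap - sigma_c) / n_c
    return sigma_b, sigma_c


def _two_level_components(
    dsq: np.ndarray,
    pop_indices: list[np.ndarray],
    pop_group: list[int],
    n_groups: int,
) -> tuple[float, float, float]:
    """(sigma_a, sigma_b, sigma_c) for populations nested in groups."""
    N = sum(len(ix) for ix in pop_indices)
    P = len(pop_indices)
    G = n_groups
    group_members: list[list[int]] = [[] for _ in range(G)]
    for p, g in enumerate(pop_group):
        group_members[g].append(p)
    all_idx = np.concatenate(pop_indices)
    ssd_total = _ssd_within(dsq, all_idx)
    ssd_wp = sum(_ssd_within(dsq, ix) for ix in pop_indices)
    ssd_wg = sum(
        _ssd_within(dsq, np.concatenate([pop_indices[p] for p in members]))
        for members in group_members
    )
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    sizes = np.array([len(ix) for ix in pop_indices], dtype=float)
    g_sizes = np.array(
        [sum(sizes[p] for p in members) for members in group_members], dtype=float
    )
    sum_np2_over_ng = sum(
        sum(sizes[p] ** 2 for p in members) / g_sizes[g]
        for g, members in enumerate(group_members)
    )
    n_1 = (N - sum_np2_over_ng) / df_ap  # coefficient for sigma_b in MS_ap
    n_2 = (sum_np2_over_ng - (sizes**2).sum() / N) / df_ag
    n_3 = (N - (g_sizes**2).sum() / N) / df_ag

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n_1
    sigma_a = (ssd_ag / df_ag - sigma_c - n_2 * sigma_b) / n_3
    return sigma_a, sigma_b, sigma_c


def _phi_from_sigma(sigma_a: float, sigma_b: float, sigma_c: float) -> dict[str, float]:
    total = sigma_a + sigma_b + sigma_c
    return {
        "Phi_CT": sigma_a / total if total else np.nan,
        "Phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else np.nan,
        "Phi_ST": (sigma_a + sigma_b) / total if total else np.nan,
    }


def _group_arrangements(pop_group: list[int], n_groups: int):
    """All distinct assignments of populations to groups preserving group sizes."""
    P = len(pop_group)
    sizes = [pop_group.count(g) for g in range(n_groups)]

    def rec(remaining: frozenset[int], g: int):
        if g == n_groups - 1:
            yield {p: g for p in remaining}
            return
        for chosen in itertools.combinations(sorted(remaining), sizes[g]):
            base = {p: g for p in chosen}
            for rest in rec(remaining - set(chosen), g + 1):
                yield {**base, **rest}

    for assignment in rec(frozenset(range(P)), 0):
        yield [assignment[p] for p in range(P)]


def amova(
    dist: np.ndarray | pd.DataFrame,
    design: HierarchicalDesign,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AMOVAResult:
    """AMOVA from a matrix of squared pairwise distances.

    ``dist`` rows must be ordered like ``design.populations``.  With
    ``design.group_of`` set, a two-level (group/population/individual)
    decomposition is produced; otherwise one-level.  ``n_perm = 0`` skips
    significance testing.
    """
    dsq = np.asarray(dist, dtype=float)
    if dsq.ndim != 2 or dsq.shape[0] != dsq.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dsq, dsq.T):
        raise ValueError("distance matrix must be symmetric")
    if dsq.shape[0] != len(design.populations):
        raise ValueError("design length does not match distance matrix")
    labels = list(design.populations)
    pops = sorted(set(labels))
    lab_arr = np.array(labels)
    pop_indices = [np.flatnonzero(lab_arr == p) for p in pops]
    singletons = [p for p, ix in zip(pops, pop_indices) if len(ix) < 2]
    if singletons:
        import warnings

        warnings.warn(
            f"singleton populations (no within-population df): {singletons}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    N = len(labels)
    P = len(pops)

    if design.group_of is None:
        sigma_b, sigma_c = _one_level_components(dsq, pop_indices)
        sigma = {"among_populations": sigma_b, "within_populations": sigma_c}
        phi_st = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else np.nan
        phi = {"Phi_ST": phi_st}
        df = {"among_populations": P - 1, "within_populations": N - P}
        all_idx = np.concatenate(pop_indices)
        ssd_total = _ssd_within(dsq, all_idx)
        ssd_wp = sum(_ssd_within(dsq, ix) for ix in pop_indices)
        ssd = {
            "among_populations": ssd_total - ssd_wp,
            "within_populations": ssd_wp,
        }
        p_values = {}
        if n_perm > 0:
            sizes = [len(ix) for ix in pop_indices]
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(N)
                start = 0
                perm_indices = []
                for s in sizes:
                    perm_indices.append(perm[start : start + s])
                    start += s
                b, c = _one_level_components(dsq, perm_indices)
                stat = b / (b + c) if (b + c) else np.nan
                if stat >= phi_st - 1e-12:
                    hits += 1
            p_values["Phi_ST"] = (hits + 1) / (n_perm + 1)
        result_sigma = (0.0, sigma_b, sigma_c)
    else:
        groups = sorted(set(design.group_of[p] for p in pops))
        g_index = {g: i for i, g in enumerate(groups)}
        pop_group = [g_index[design.group_of[p]] for p in pops]
        G = len(groups)
        sigma_a, sigma_b, sigma_c = _two_level_components(
            dsq, pop_indices, pop_group, G
        )
        sigma = {
            "among_groups": sigma_a,
            "among_populations_within_groups": sigma_b,
            "within_populations": sigma_c,
        }
        phi = _phi_from_sigma(sigma_a, sigma_b, sigma_c)
        df = {
            "among_groups": G - 1,
            "among_populations_within_groups": P - G,
            "within_populations": N - P,
        }
        all_idx = np.concatenate(pop_indices)
        group_members: list[list[int]] = [[] for _ in range(G)]
        for p, g in enumerate(pop_group):
            group_members[g].append(p)
        ssd_total = _ssd_within(dsq, all_idx)
        ssd_wp = sum(_ssd_within(dsq, ix) for ix in pop_indices)
        ssd_wg = sum(
            _ssd_within(dsq, np.concatenate([pop_indices[p] for p in members]))
            for members in group_members
        )
        ssd = {
            "among_groups": ssd_total - ssd_wg,
            "among_populations_within_groups": ssd_wg - ssd_wp,
            "within_populations": ssd_wp,
        }
        p_values = {}
        exact_ct = False
        if n_perm > 0:
            sizes = [len(ix) for ix in pop_indices]
            # Phi_ST: individuals among populations, whole sample
            hits_st = 0
            for _ in range(n_perm):
                perm = rng.permutation(N)
                start = 0
                perm_indices = []
                for s in sizes:
                    perm_indices.append(perm[start : start + s])
                    start += s
                a, b, c = _two_level_components(dsq, perm_indices, pop_group, G)
                stat = _phi_from_sigma(a, b, c)["Phi_ST"]
                if stat >= phi["Phi_ST"] - 1e-12:
                    hits_st += 1
            p_values["Phi_ST"] = (hits_st + 1) / (n_perm + 1)
            # Phi_SC: individuals among populations within groups
            hits_sc = 0
            for _ in range(n_perm):
                perm_indices = [None] * P
                for members in group_members:
                    pool = np.concatenate([pop_indices[p] for p in members])
                    pool = rng.permutation(pool)
                    start = 0
                    for p in members:
                        perm_indices[p] = pool[start : start + sizes[p]]
                        start += sizes[p]
                a, b, c = _two_level_components(dsq, perm_indices, pop_group, G)
                stat = _phi_from_sigma(a, b, c)["Phi_SC"]
                if stat >= phi["Phi_SC"] - 1e-12:
                    hits_sc += 1
            p_values["Phi_SC"] = (hits_sc + 1) / (n_perm + 1)
            # Phi_CT: whole populations among groups; enumerate when feasible
            arrangements = list(itertools.islice(_group_arrangements(pop_group, G), n_perm + 1))
            if len(arrangements) <= n_perm:
                exact_ct = True
                hits_ct = 0
                for arr in arrangements:
                    a, b, c = _two_level_components(dsq, pop_indices, arr, G)
                    stat = _phi_from_sigma(a, b, c)["Phi_CT"]
                    if stat >= phi["Phi_CT"] - 1e-12:
                        hits_ct += 1
                p_values["Phi_CT"] = hits_ct / len(arrangements)
            else:
                hits_ct = 0
                for _ in range(n_perm):
                    arr = list(rng.permutation(pop_group))
                    a, b, c = _two_level_components(dsq, pop_indices, arr, G)
                    stat = _phi_from_sigma(a, b, c)["Phi_CT"]
                    if stat >= phi["Phi_CT"] - 1e-12:
                        hits_ct += 1
                p_values["Phi_CT"] = (hits_ct + 1) / (n_perm + 1)
        result_sigma = (sigma_a, sigma_b, sigma_c)

    truncated = {k: max(v, 0.0) for k, v in sigma.items()}
    tot = sum(truncated.values())
    percent = {k: (100.0 * v / tot if tot else np.nan) for k, v in truncated.items()}
    return AMOVAResult(
        df=df,
        ssd=ssd,
        sigma=sigma,
        percent=percent,
        phi=phi,
        p_values=p_values,
        negative_component=any(v < 0 for v in sigma.values()),
        n_permutations=n_perm,
        exact_ct=design.group_of is not None and n_perm > 0 and exact_ct,
    )


def pairwise_phi_st(
    dist: np.ndarray | pd.DataFrame,
    populations: tuple[str, ...] | list[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    bonferroni_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi_ST: each population pair analysed as a two-population AMOVA.

    Returns (phi_matrix, p_matrix, significant_after_bonferroni).
    """
    dsq = np.asarray(dist, dtype=float)
    lab_arr = np.array(list(populations))
    pops = sorted(set(populations))
    phi_m = pd.DataFrame(0.0, index=pops, columns=pops)
    p_m = pd.DataFrame(np.nan, index=pops, columns=pops)
    pairs = list(itertools.combinations(pops, 2))
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        mask = (lab_arr == a) | (lab_arr == b)
        idx = np.flatnonzero(mask)
        sub = dsq[np.ix_(idx, idx)]
        sub_design = HierarchicalDesign(tuple(lab_arr[idx]))
        res = amova(
            sub, sub_design, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        phi_m.loc[a, b] = phi_m.loc[b, a] = res.phi["Phi_ST"]
        if n_perm > 0:
            p_m.loc[a, b] = p_m.loc[b, a] = res.p_values["Phi_ST"]
    alpha_adj = bonferroni_alpha / len(pairs) if pairs else bonferroni_alpha
    sig = p_m <= alpha_adj
    return phi_m, p_m, sig
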