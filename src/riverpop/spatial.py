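"""Isolation-by-distance: Mantel test of linearized differentiation vs distance.

The genetic matrix is linearized as d/(1-d) (Rousset) and geographic
distances are log10-transformed kilometres; the correlation is Pearson's r
over unordered pairs and significance comes from permuting population order
in one matrix.  Distances are expected to be supplied by the user (e.g.
along-river waterway kilometres); a great-circle helper is provided for
convenience but is not the default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IBDResult", "mantel_ibd", "great_circle_km"]


@dataclass(frozen=True)
class IBDResult:
    r: float
    p_value: float
    n_populations: int
    n_pairs_used: int
    n_perm: int
    exact: bool
    alternative: str
    seed: int | None = None


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance between (lat, lon) points in km."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * 6371.0 * math.asin(math.sqrt(h))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x**2).sum() * (y**2).sum())
    return float((x * y).sum() / denom) if denom else math.nan


def mantel_ibd(
    gen_dist: pd.DataFrame,
    geo_km: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    linearize: bool = True,
    log10_distance: bool = True,
    alternative: str = "two-sided",
) -> IBDResult:
    """Mantel correlation between d/(1-d) and log10(km) with permutation P.

    Pairs with genetic distance >= 1 (linearization undefined) or zero
    geographic distance (log undefined) are excluded with a warning.  With
    few populations the permutation space is enumerated exactly.
    ``alternative`` is "two-sided" (|r|) or "greater" (positive IBD).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    pops = list(gen_dist.index)
    if list(geo_km.index) != pops or list(geo_km.columns) != pops:
        geo_km = geo_km.loc[pops, pops]
    g = np.asarray(gen_dist, dtype=float)
    e = np.asarray(geo_km, dtype=float)
    npop = len(pops)
    if npop < 4:
        warnings.warn(
            "fewer than 4 populations: permutation space is tiny, "
            "enumerating exactly",
            stacklevel=2,
        )
    iu = np.triu_indices(npop, k=1)
    mask = np.ones(npop * (npop - 1) // 2, dtype=bool)
    if linearize:
        bad = g[iu] >= 1.0
        if bad.any():
            warnings.warn(
                f"excluding {int(bad.sum())} pair(s) with genetic distance >= 1",
                stacklevel=2,
            )
            mask &= ~bad
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(g < 1.0, g / (1.0 - g), np.nan)
    if log10_distance:
        zero = e[iu] <= 0.0
        if zero.any():
            warnings.warn(
                f"excluding {int(zero.sum())} pair(s) with non-positive distance",
                stacklevel=2,
            )
            mask &= ~zero
        with np.errstate(divide="ignore"):
            e = np.where(e > 0, np.log10(e), np.nan)
    x = e[iu]
    y_obs = g[iu]

    def r_for(order: np.ndarray) -> float:
        gp = g[np.ix_(order, order)]
        return _pearson(x[mask], gp[iu][mask])

    r_obs = _pearson(x[mask], y_obs[mask])

    def extreme(r: float) -> bool:
        if alternative == "two-sided":
            return abs(r) >= abs(r_obs) - 1e-12
        return r >= r_obs - 1e-12

    n_total = math.factorial(npop)
    exact = n_total <= n_perm
    if exact:
        hits = sum(
            extreme(r_for(np.array(perm)))
            for perm in itertools.permutations(range(npop))
        )
        p = hits / n_total
        n_used = n_total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if extreme(r_for(rng.permutation(npop))):
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        n_used = n_perm
    return IBDResult(
        r=r_obs,
        p_value=p,
        n_populations=npop,
        n_pairs_used=int(mask.sum()),
        n_perm=n_used,
        exact=exact,
        alternative=alternative,
        seed=seed,
    )
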