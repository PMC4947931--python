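"""Independent brute-force reference implementations used by unit and
acceptance tests.  These deliberately avoid the package's own code paths:
everything is computed by direct enumeration from first principles."""

from __future__ import annotations

import itertools
import math

import numpy as np


def hd_brute(counts) -> float:
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    return n / (n - 1) * (1.0 - sum((c / n) ** 2 for c in counts))


def pair_diff_brute(a: str, b: str) -> tuple[int, int]:
    """(differences, compared sites) with pairwise deletion of non-ACGT."""
    diff = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            if x != y:
                diff += 1
    return diff, comp


def pi_k_brute(seqs) -> tuple[float, float]:
    diffs, comps = [], []
    for a, b in itertools.combinations(seqs, 2):
        d, c = pair_diff_brute(a, b)
        diffs.append(d)
        comps.append(c)
    K = sum(diffs) / len(diffs)
    return K / (sum(comps) / len(comps)), K


def k2p_brute(a: str, b: str) -> float:
    ts = tv = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        comp += 1
        if x == y:
            continue
        purine = set("AG")
        if (x in purine) == (y in purine):
            ts += 1
        else:
            tv += 1
    P, Q = ts / comp, tv / comp
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def nested_anova_components(x: np.ndarray, pops: list, groups: list):
    """Classical nested ANOVA components from coordinates (unequal sizes).

    ``x`` is (n, dims); population and group label per row.  Returns
    (sigma_a, sigma_b, sigma_c) for among-group / among-pop-in-group /
    within-pop, using textbook expected-mean-square coefficients.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    pops = np.asarray(pops)
    groups = np.asarray(groups)
    N = len(x)
    pop_list = sorted(set(pops.tolist()))
    group_list = sorted(set(groups.tolist()))
    grand = x.mean(axis=0)
    ss_wp = 0.0
    ss_ap_wg = 0.0
    ss_ag = 0.0
    group_of_pop = {}
    for p in pop_list:
        sel = pops == p
        group_of_pop[p] = groups[sel][0]
        mean_p = x[sel].mean(axis=0)
        ss_wp += float(((x[sel] - mean_p) ** 2).sum())
    for g in group_list:
        sel = groups == g
        mean_g = x[sel].mean(axis=0)
        ss_ag += sel.sum() * float(((mean_g - grand) ** 2).sum())
        for p in pop_list:
            if group_of_pop[p] != g:
                continue
            selp = pops == p
            mean_p = x[selp].mean(axis=0)
            ss_ap_wg += selp.sum() * float(((mean_p - mean_g) ** 2).sum())
    P, G = len(pop_list), len(group_list)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    sizes = {p: int((pops == p).sum()) for p in pop_list}
    gsizes = {g: int((groups == g).sum()) for g in group_list}
    sum_np2_over_ng = sum(
        sizes[p] ** 2 / gsizes[group_of_pop[p]] for p in pop_list
    )
    n1 = (N - sum_np2_over_ng) / df_ap
    n2 = (sum_np2_over_ng - sum(s**2 for s in sizes.values()) / N) / df_ag
    n3 = (N - sum(s**2 for s in gsizes.values()) / N) / df_ag
    sigma_c = ss_wp / df_wp
    sigma_b = (ss_ap_wg / df_ap - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def one_level_anova_components(x: np.ndarray, pops: list):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    pops = np.asarray(pops)
    N = len(x)
    pop_list = sorted(set(pops.tolist()))
    grand = x.mean(axis=0)
    ss_wp = ss_ap = 0.0
    for p in pop_list:
        sel = pops == p
        mean_p = x[sel].mean(axis=0)
        ss_wp += float(((x[sel] - mean_p) ** 2).sum())
        ss_ap += sel.sum() * float(((mean_p - grand) ** 2).sum())
    P = len(pop_list)
    sizes = {p: int((pops == p).sum()) for p in pop_list}
    n_c = (N - sum(s**2 for s in sizes.values()) / N) / (P - 1)
    sigma_c = ss_wp / (N - P)
    sigma_b = (ss_ap / (P - 1) - sigma_c) / n_c
    return sigma_b, sigma_c


def ewens_pmf_crp(n: int, theta: float) -> list[float]:
    """Pr(K=k), k=1..n via the Chinese-restaurant-process recursion
    (independent of the Stirling-number formula)."""
    probs = {1: {1: 1.0}}
    for m in range(1, n):
        nxt: dict[int, float] = {}
        for k, pr in probs[m].items():
            nxt[k] = nxt.get(k, 0.0) + pr * m / (theta + m)
            nxt[k + 1] = nxt.get(k + 1, 0.0) + pr * theta / (theta + m)
        probs[m + 1] = nxt
    return [probs[n].get(k, 0.0) for k in range(1, n + 1)]


def fs_brute(n: int, h: int, theta: float) -> float:
    pmf = ewens_pmf_crp(n, theta)
    s_prime = sum(pmf[h - 1 :])
    return math.log(s_prime / (1.0 - s_prime))


def raggedness_brute(freqs) -> float:
    x = list(freqs)
    while len(x) > 1 and x[-1] == 0:
        x.pop()
    x.append(0.0)
    return sum((x[i] - x[i - 1]) ** 2 for i in range(1, len(x)))


def nei_unbiased_brute(pa, pb, na: int, nb: int) -> float:
    """Nei 1978 unbiased D for biallelic columns with freqs pa, pb."""
    jxy = float(np.mean([p * q + (1 - p) * (1 - q) for p, q in zip(pa, pb)]))
    jx = float(
        np.mean(
            [(2 * na * (p**2 + (1 - p) ** 2) - 1) / (2 * na - 1) for p in pa]
        )
    )
    jy = float(
        np.mean(
            [(2 * nb * (q**2 + (1 - q) ** 2) - 1) / (2 * nb - 1) for q in pb]
        )
    )
    return -math.log(jxy / math.sqrt(jx * jy))
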