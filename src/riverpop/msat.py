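"""Polyploid microsatellite band-phenotype analysis.

Tetraploid band data carry no allele dosage, so every locus is treated as
dominant: the multilocus band phenotype of each individual is transformed to
a binary presence/absence vector with one column per observed (locus, band)
combination.  Diversity (PPL, Nei's H, Shannon's I), Nei's unbiased distance,
distance-based F_ST (via AMOVA on squared Euclidean row distances), PCoA and
the Evanno delta-K post-processing all operate on that encoding.

Band frequency ``p`` is by default the *phenotype* frequency (fraction of
individuals showing the band) rather than a Hardy-Weinberg-derived allele
frequency, because auto- vs allotetraploidy is generally unknown; the
``hwe_dominant`` flag switches to the sqrt-based dominant-marker estimator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amova import AMOVAResult, HierarchicalDesign, amova, pairwise_phi_st

__all__ = [
    "BandPhenotypeMatrix",
    "BinaryMatrix",
    "phenotypes_to_binary",
    "band_diversity",
    "nei_unbiased_distance",
    "binary_fst",
    "pcoa",
    "evanno_delta_k",
]

MAX_BANDS = 4  # tetraploid genome: at most 4 distinct alleles per locus


@dataclass(frozen=True)
class BandPhenotypeMatrix:
    """Individuals x loci -> tuple of observed band sizes (1..4 per cell)."""

    data: pd.DataFrame  # cells: tuple[int, ...] or None for missing score
    population: dict[str, str]

    def __post_init__(self) -> None:
        for ind in self.data.index:
            for locus in self.data.columns:
                bands = self.data.loc[ind, locus]
                if bands is None:
                    continue
                if not 1 <= len(bands) <= MAX_BANDS:
                    raise ValueError(
                        f"{ind}/{locus}: {len(bands)} bands (allowed 1..{MAX_BANDS})"
                    )
                if any(b <= 0 for b in bands):
                    raise ValueError(f"{ind}/{locus}: non-positive band size")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "BandPhenotypeMatrix":
        """From long format with columns individual, population, locus, bands
        (tuple, or comma-separated string of sizes)."""
        df = df.copy()
        df["bands"] = df["bands"].apply(
            lambda b: tuple(sorted(int(x) for x in str(b).split(",")))
            if not isinstance(b, tuple)
            else b
        )
        wide = df.pivot(index="individual", columns="locus", values="bands")
        wide = wide.where(pd.notna(wide), None)
        pops = dict(zip(df["individual"], df["population"]))
        return cls(wide, pops)

    @classmethod
    def read_table(cls, path) -> "BandPhenotypeMatrix":
        """Delimited text: individual, population, locus, comma-joined sizes."""
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
        df.columns = ["individual", "population", "locus", "bands"]
        return cls.from_long(df)

    def write_table(self, path) -> None:
        rows = []
        for ind in self.data.index:
            for locus in self.data.columns:
                bands = self.data.loc[ind, locus]
                if bands is None:
                    continue
                rows.append(
                    {
                        "individual": ind,
                        "population": self.population[ind],
                        "locus": locus,
                        "bands": ",".join(str(b) for b in bands),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class BinaryMatrix:
    """Presence/absence per (locus, band) column; NaN marks missing locus scores."""

    data: pd.DataFrame  # float with {0.0, 1.0, NaN}
    population: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.data.index:
            seen.setdefault(self.population[ind], None)
        return list(seen)

    def pop_labels(self) -> list[str]:
        return [self.population[i] for i in self.data.index]

    def to_band_sets(self) -> BandPhenotypeMatrix:
        """Inverse of the binary transform (presence information is lossless)."""
        loci: dict[str, list[tuple[str, int]]] = {}
        for col in self.data.columns:
            locus, band = col.rsplit(":", 1)
            loci.setdefault(locus, []).append((col, int(band)))
        cells = {}
        for ind in self.data.index:
            row = {}
            for locus, cols in loci.items():
                vals = [self.data.loc[ind, c] for c, _ in cols]
                if all(pd.isna(v) for v in vals):
                    row[locus] = None
                else:
                    row[locus] = tuple(
                        sorted(b for (c, b), v in zip(cols, vals) if v == 1.0)
                    )
            cells[ind] = row
        df = pd.DataFrame.from_dict(cells, orient="index")
        df = df.reindex(index=self.data.index, columns=sorted(loci))
        return BandPhenotypeMatrix(df, self.population)


def phenotypes_to_binary(bpm: BandPhenotypeMatrix) -> BinaryMatrix:
    """One column per observed (locus, band); copy number discarded.

    A missing locus score yields NaN across that locus's columns, distinct
    from scored absence (0).
    """
    columns: list[str] = []
    per_locus_bands: dict[str, list[int]] = {}
    for locus in bpm.loci:
        bands = sorted(
            {
                b
                for cell in bpm.data[locus]
                if cell is not None
                for b in cell
            }
        )
        per_locus_bands[locus] = bands
        columns.extend(f"{locus}:{b}" for b in bands)
    mat = np.full((len(bpm.individuals), len(columns)), np.nan)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, ind in enumerate(bpm.individuals):
        for locus in bpm.loci:
            cell = bpm.data.loc[ind, locus]
            if cell is None:
                continue
            for b in per_locus_bands[locus]:
                mat[i, col_index[f"{locus}:{b}"]] = 1.0 if b in cell else 0.0
    df = pd.DataFrame(mat, index=bpm.individuals, columns=columns)
    return BinaryMatrix(df, bpm.population)


def _band_frequencies(bin_: BinaryMatrix, pop: str) -> pd.Series:
    members = [i for i in bin_.data.index if bin_.population[i] == pop]
    if not members:
        raise ValueError(f"empty population {pop!r}")
    return bin_.data.loc[members].mean(axis=0, skipna=True)


def band_diversity(
    bin_: BinaryMatrix, hwe_dominant: bool = False, ppl_criterion: float = 1.0
) -> pd.DataFrame:
    """Per-population Total/Private bands, PPL (%), Nei's H and Shannon's I.

    Per band: H = 2p(1-p) and I = -[p ln p + (1-p) ln(1-p)] with p the band
    presence frequency (``hwe_dominant`` replaces p by the allele frequency
    1 - sqrt(1-p) first).  Population values are means over all binary
    columns; PPL counts columns with 0 < p < ``ppl_criterion``.
    """
    pops = bin_.populations
    presence = {p: _band_frequencies(bin_, p) for p in pops}
    present_sets = {p: set(presence[p][presence[p] > 0].index) for p in pops}
    rows = {}
    for pop in pops:
        p = presence[pop].to_numpy(dtype=float)
        if hwe_dominant:
            p = 1.0 - np.sqrt(np.clip(1.0 - p, 0.0, 1.0))
        h = 2.0 * p * (1.0 - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            i_term = -(
                np.where(p > 0, p * np.log(p), 0.0)
                + np.where(p < 1, (1.0 - p) * np.log(1.0 - p), 0.0)
            )
        poly = (p > 0) & (p < ppl_criterion)
        others = set().union(
            *(present_sets[q] for q in pops if q != pop)
        ) if len(pops) > 1 else set()
        rows[pop] = {
            "n": sum(1 for i in bin_.data.index if bin_.population[i] == pop),
            "total_bands": int(len(present_sets[pop])),
            "private_bands": int(len(present_sets[pop] - others)),
            "PPL": 100.0 * poly.mean(),
            "H": float(np.nanmean(h)),
            "I": float(np.nanmean(i_term)),
        }
    return pd.DataFrame(rows).T


def nei_unbiased_distance(bin_: BinaryMatrix) -> pd.DataFrame:
    """Nei (1978) unbiased distance between populations from band frequencies.

    Each binary column is treated as a biallelic locus with frequencies
    (p, 1-p).  Identities use the unbiased correction
    J_X = (2n sum p_i^2 - 1)/(2n - 1); D = -ln( J_XY / sqrt(J_X J_Y) ),
    identities averaged over columns.  Zero shared identity is flagged and
    capped at D = inf.
    """
    pops = bin_.populations
    freqs = {}
    sizes = {}
    for pop in pops:
        members = [i for i in bin_.data.index if bin_.population[i] == pop]
        sizes[pop] = len(members)
        if len(members) < 2:
            warnings.warn(
                f"population {pop!r} has n < 2: unbiased correction undefined, "
                "using plain identity",
                stacklevel=2,
            )
        freqs[pop] = bin_.data.loc[members].mean(axis=0, skipna=True).to_numpy()

    def j_within(pop: str) -> np.ndarray:
        p = freqs[pop]
        raw = p**2 + (1.0 - p) ** 2
        n = sizes[pop]
        if n < 2:
            return raw
        return (2 * n * raw - 1.0) / (2 * n - 1.0)

    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        pa, pb = freqs[a], freqs[b]
        jxy = float(np.nanmean(pa * pb + (1.0 - pa) * (1.0 - pb)))
        jx = float(np.nanmean(j_within(a)))
        jy = float(np.nanmean(j_within(b)))
        if jxy <= 0:
            warnings.warn(
                f"no shared identity between {a!r} and {b!r}: D capped at inf",
                stacklevel=2,
            )
            d = math.inf
        else:
            d = -math.log(jxy / math.sqrt(jx * jy))
        out.loc[a, b] = out.loc[b, a] = d
    return out


def binary_squared_distances(bin_: BinaryMatrix) -> np.ndarray:
    """Squared Euclidean distance between binary rows (pairwise deletion of
    missing scores, rescaled to the full column count)."""
    x = bin_.data.to_numpy(dtype=float)
    n, m = x.shape
    out = np.zeros((n, n))
    valid = ~np.isnan(x)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = np.where(both, (x[i] - x[i + 1 :]) ** 2, 0.0)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i, i + 1 :] = diff.sum(axis=1) * (m / np.maximum(cnt, 1))
    out += out.T
    return out


def binary_fst(
    bin_: BinaryMatrix,
    region_of: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[AMOVAResult, pd.DataFrame, pd.DataFrame]:
    """Distance-based F_ST from binary data: AMOVA on squared Euclidean rows.

    Returns (amova_result, pairwise_fst, pairwise_p).  ``region_of`` switches
    to the two-level design.
    """
    dsq = binary_squared_distances(bin_)
    pops = tuple(bin_.pop_labels())
    design = HierarchicalDesign(pops, region_of)
    res = amova(dsq, design, n_perm=n_perm, seed=seed)
    fst, pvals, _ = pairwise_phi_st(dsq, pops, n_perm=n_perm, seed=seed)
    return res, fst, pvals


def pcoa(dist: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal coordinates via Gower double centering.

    Returns (coordinates from positive axes, all eigenvalues descending,
    percent of positive variance per positive axis).
    """
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    centered = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    coords_df = pd.DataFrame(
        coords,
        index=labels if labels is not None else range(n),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return coords_df, eigval, pct


def evanno_delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Evanno delta-K from a replicate table of clustering log-likelihoods.

    ``lnp`` must have columns ``K`` and ``lnP`` (one row per replicate run).
    Returns per-K mean, sd, |L'(K)|, |L''(K)| and delta K (defined for
    interior K only; NaN and flagged where sd = 0).
    """
    if not {"K", "lnP"} <= set(lnp.columns):
        raise ValueError("need columns 'K' and 'lnP'")
    grouped = lnp.groupby("K")["lnP"]
    ks = sorted(grouped.groups)
    if len(ks) < 3:
        raise ValueError("delta K needs >= 3 consecutive K values")
    if (np.diff(ks) != 1).any():
        raise ValueError("K values must be consecutive")
    if (grouped.count() < 2).any():
        raise ValueError("delta K needs >= 2 replicates per K")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    rows = []
    for i, k in enumerate(ks):
        rec = {"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k]}
        if 0 < i < len(ks) - 1:
            l2 = abs(mean[ks[i + 1]] - 2 * mean[k] + mean[ks[i - 1]])
            rec["abs_L2"] = l2
            rec["delta_K"] = l2 / sd[k] if sd[k] > 0 else np.nan
        else:
            rec["abs_L2"] = np.nan
            rec["delta_K"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("K")
    if out["delta_K"].notna().any():
        out.attrs["best_K"] = int(out["delta_K"].idxmax())
    return out
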