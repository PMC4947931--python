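import math

import numpy as np
import pandas as pd
import pytest

from riverpop.msat import (
    BandPhenotypeMatrix,
    band_diversity,
    binary_fst,
    binary_squared_distances,
    evanno_delta_k,
    nei_unbiased_distance,
    pcoa,
    phenotypes_to_binary,
)

from .oracles import nei_unbiased_brute


def _bpm(rows):
    """rows: (individual, population, locus, bands-tuple)."""
    df = pd.DataFrame(
        rows, columns=["individual", "population", "locus", "bands"]
    )
    return BandPhenotypeMatrix.from_long(df)


@pytest.fixture
def toy_bands():
    return _bpm(
        [
            ("i1", "A", "L1", (151, 155)),
            ("i1", "A", "L2", (200,)),
            ("i2", "A", "L1", (151,)),
            ("i2", "A", "L2", (200, 204)),
            ("i3", "B", "L1", (155, 159)),
            ("i3", "B", "L2", (200,)),
            ("i4", "B", "L1", (151, 155)),
            ("i4", "B", "L2", (208,)),
        ]
    )


class TestBinaryTransform:
    def test_hand_checked(self, toy_bands):
        b = phenotypes_to_binary(toy_bands)
        assert list(b.data.columns) == [
            "L1:151", "L1:155", "L1:159", "L2:200", "L2:204", "L2:208",
        ]
        assert b.data.loc["i1"].tolist() == [1, 1, 0, 1, 0, 0]
        assert b.data.loc["i3"].tolist() == [0, 1, 1, 1, 0, 0]

    def test_column_count(self, toy_bands):
        b = phenotypes_to_binary(toy_bands)
        assert b.data.shape[1] == 3 + 3  # distinct bands per locus

    def test_too_many_bands_error(self):
        with pytest.raises(ValueError, match="i1/L1"):
            _bpm([("i1", "A", "L1", (1, 2, 3, 4, 5))])

    def test_lossless_round_trip(self, toy_bands):
        b = phenotypes_to_binary(toy_bands)
        back = b.to_band_sets()
        assert back.data.equals(toy_bands.data.sort_index(axis=1))

    def test_missing_score_is_nan_not_zero(self):
        bpm = _bpm(
            [
                ("i1", "A", "L1", (10,)),
                ("i1", "A", "L2", (20,)),
                ("i2", "A", "L1", (10,)),
            ]
        )
        b = phenotypes_to_binary(bpm)
        assert np.isnan(b.data.loc["i2", "L2:20"])

    def test_table_io_round_trip(self, toy_bands, tmp_path):
        p = tmp_path / "bands.csv"
        toy_bands.write_table(p)
        back = BandPhenotypeMatrix.read_table(p)
        assert back.data.equals(toy_bands.data)
        assert back.population == toy_bands.population


class TestBandDiversity:
    def test_p_half_values(self):
        bpm = _bpm(
            [
                ("i1", "A", "L1", (1,)),
                ("i2", "A", "L1", (2,)),
            ]
        )
        rep = band_diversity(phenotypes_to_binary(bpm))
        # both columns have p = 0.5: H = 0.5, I = ln 2
        assert rep.loc["A", "H"] == pytest.approx(0.5)
        assert rep.loc["A", "I"] == pytest.approx(math.log(2), abs=1e-6)
        assert rep.loc["A", "PPL"] == pytest.approx(100.0)

    def test_monomorphic_band(self):
        bpm = _bpm(
            [
                ("i1", "A", "L1", (1,)),
                ("i2", "A", "L1", (1,)),
            ]
        )
        rep = band_diversity(phenotypes_to_binary(bpm))
        assert rep.loc["A", "H"] == 0.0
        assert rep.loc["A", "I"] == 0.0
        assert rep.loc["A", "PPL"] == 0.0

    def test_private_bands(self, toy_bands):
        rep = band_diversity(phenotypes_to_binary(toy_bands))
        # L1:159 and L2:208 occur only in B; L2:204 only in A
        assert rep.loc["A", "private_bands"] == 1
        assert rep.loc["B", "private_bands"] == 2

    def test_brute_force_small(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, size=(8, 10)).astype(float)
        mat[:, 0] = 1.0  # keep rows non-empty
        from riverpop.msat import BinaryMatrix

        df = pd.DataFrame(
            mat,
            index=[f"i{r}" for r in range(8)],
            columns=[f"L1:{c}" for c in range(10)],
        )
        b = BinaryMatrix(df, {f"i{r}": "A" for r in range(8)})
        rep = band_diversity(b)
        p = mat.mean(axis=0)
        H = np.mean(2 * p * (1 - p))
        terms = []
        for q in p:
            t = 0.0
            if q > 0:
                t -= q * math.log(q)
            if q < 1:
                t -= (1 - q) * math.log(1 - q)
            terms.append(t)
        assert rep.loc["A", "H"] == pytest.approx(H, abs=1e-12)
        assert rep.loc["A", "I"] == pytest.approx(np.mean(terms), abs=1e-12)
        assert rep.loc["A", "PPL"] == pytest.approx(
            100.0 * np.mean((p > 0) & (p < 1)), abs=1e-12
        )

    def test_hwe_dominant_flag_changes_values(self, toy_bands):
        b = phenotypes_to_binary(toy_bands)
        direct = band_diversity(b)
        hwe = band_diversity(b, hwe_dominant=True)
        assert not direct["H"].equals(hwe["H"])

    def test_h_bounded_by_half(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(12):
            rows.append((f"i{i}", "A", "L1", tuple(sorted(set(rng.integers(1, 6, 3))))))
        rep = band_diversity(phenotypes_to_binary(_bpm(rows)))
        assert 0 <= rep.loc["A", "H"] <= 0.5


class TestNeiDistance:
    def test_identical_zero(self):
        bpm = _bpm(
            [
                ("i1", "A", "L1", (1, 2)),
                ("i2", "A", "L1", (1, 2)),
                ("i3", "B", "L1", (1, 2)),
                ("i4", "B", "L1", (1, 2)),
            ]
        )
        d = nei_unbiased_distance(phenotypes_to_binary(bpm))
        assert d.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self, toy_bands):
        b = phenotypes_to_binary(toy_bands)
        d = nei_unbiased_distance(b)
        pa = b.data.loc[["i1", "i2"]].mean().to_numpy()
        pb = b.data.loc[["i3", "i4"]].mean().to_numpy()
        assert d.loc["A", "B"] == pytest.approx(
            nei_unbiased_brute(pa, pb, 2, 2), abs=1e-12
        )

    def test_symmetric_zero_diagonal(self, toy_bands):
        d = nei_unbiased_distance(phenotypes_to_binary(toy_bands))
        assert d.loc["A", "A"] == 0.0
        assert d.loc["A", "B"] == d.loc["B", "A"]


class TestBinaryFst:
    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(16):
            pop = "A" if i < 8 else "B"
            bands = tuple(sorted(set(rng.integers(1, 8, size=3))))
            rows.append((f"i{i}", pop, "L1", bands))
        res, fst, _ = binary_fst(_to_bin(rows), n_perm=99, seed=0)
        assert abs(res.phi["Phi_ST"]) < 0.15

    def test_fully_distinct_is_one(self):
        rows = []
        for i in range(6):
            rows.append((f"i{i}", "A", "L1", (1, 2)))
        for i in range(6, 12):
            rows.append((f"i{i}", "B", "L1", (7, 8)))
        res, fst, _ = binary_fst(_to_bin(rows), n_perm=0)
        assert res.phi["Phi_ST"] == pytest.approx(1.0)

    def test_fct_recovery_single(self):
        from riverpop.amova import HierarchicalDesign, amova
        from riverpop.simulate import simulate_binary_hierarchy

        n_per_pop = {"w1": 15, "w2": 15, "e1": 15, "e2": 15}
        region_of = {"w1": "w", "w2": "w", "e1": "e", "e2": "e"}
        fcts = []
        for seed in range(15):
            df, pops = simulate_binary_hierarchy(
                n_per_pop, region_of, n_cols=150, fct=0.09, seed=seed
            )
            x = df.to_numpy(dtype=float)
            dsq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
            res = amova(
                dsq, HierarchicalDesign(tuple(pops), region_of), n_perm=0
            )
            fcts.append(res.phi["Phi_CT"])
        assert np.mean(fcts) == pytest.approx(0.09, abs=0.03)


def _to_bin(rows):
    return phenotypes_to_binary(_bpm(rows))


class TestPcoa:
    def test_line_first_axis_everything(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        coords, eigval, pct = pcoa(pd.DataFrame(d))
        assert pct[0] == pytest.approx(100.0)

    def test_2d_recovery_procrustes(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(axis=2))
        coords, _, pct = pcoa(pd.DataFrame(d))
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, coords.to_numpy()[:, :2])
        assert disparity < 1e-12

    def test_eigenvalue_sum_is_trace(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(axis=2))
        coords, eigval, _ = pcoa(pd.DataFrame(d))
        a = -0.5 * d**2
        centered = (
            a - a.mean(1, keepdims=True) - a.mean(0, keepdims=True) + a.mean()
        )
        assert eigval.sum() == pytest.approx(np.trace(centered), abs=1e-8)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(axis=2))
        ours, eigval, _ = pcoa(pd.DataFrame(d))
        theirs = sk_pcoa(d, number_of_dimensions=4)
        assert np.allclose(
            np.sort(eigval)[::-1][:4], theirs.eigvals.to_numpy()[:4], atol=1e-8
        )
        assert np.allclose(
            np.abs(ours.to_numpy()[:, :3]),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )


class TestEvannoDeltaK:
    def _table(self, means, reps=3, jitter=(-1.0, 0.0, 1.0)):
        rows = []
        for k, m in means.items():
            for j in jitter[:reps]:
                rows.append({"K": k, "lnP": m + j})
        return pd.DataFrame(rows)

    def test_linear_means_zero_delta(self):
        t = evanno_delta_k(self._table({1: -100, 2: -90, 3: -80, 4: -70}))
        inner = t.loc[[2, 3], "delta_K"]
        assert np.allclose(inner, 0.0)

    def test_elbow_at_three(self):
        means = {1: -500, 2: -400, 3: -300, 4: -295, 5: -290}
        t = evanno_delta_k(self._table(means))
        assert t.attrs["best_K"] == 3

    def test_scaling_invariance(self):
        means = {1: -500, 2: -400, 3: -300, 4: -295, 5: -290}
        t1 = evanno_delta_k(self._table(means))
        t2 = evanno_delta_k(
            self._table({k: 2.5 * v for k, v in means.items()}, jitter=(-2.5, 0.0, 2.5))
        )
        assert t1.attrs["best_K"] == t2.attrs["best_K"]
        assert np.allclose(
            t1["delta_K"].dropna(), t2["delta_K"].dropna(), atol=1e-9
        )

    def test_zero_sd_flagged(self):
        rows = []
        for k in (1, 2, 3):
            for _ in range(2):
                rows.append({"K": k, "lnP": -100.0 * k})
        t = evanno_delta_k(pd.DataFrame(rows))
        assert np.isnan(t.loc[2, "delta_K"])

    def test_validation(self):
        with pytest.raises(ValueError):
            evanno_delta_k(pd.DataFrame({"K": [1, 2], "lnP": [1.0, 2.0]}))
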