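"""Single-cell qRT-PCR preprocessing: Log2Ex, LoD adjustment, filtering,
clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.ndimage import gaussian_filter1d

from klrpath import scqpcr, synth


def ct_matrix(values: dict, lod=None, **kw) -> scqpcr.CtMatrix:
    return scqpcr.CtMatrix(pd.DataFrame(values), lod=lod, **kw)


class TestComputeLog2ex:
    def test_direct_subtraction(self):
        ct = ct_matrix({"g": [20.0]})
        out = scqpcr.compute_log2ex(ct)
        assert out.values.iloc[0, 0] == 4.0
        assert bool(out.expressed.iloc[0, 0])

    def test_boundary_at_lod_is_non_expressed(self):
        ct = ct_matrix({"g": [24.0]})
        out = scqpcr.compute_log2ex(ct)
        assert out.values.iloc[0, 0] == 0.0
        assert not bool(out.expressed.iloc[0, 0])

    def test_missing_ct_is_non_expressed(self):
        ct = ct_matrix({"g": [np.nan]})
        out = scqpcr.compute_log2ex(ct)
        assert out.values.iloc[0, 0] == 0.0
        assert not bool(out.expressed.iloc[0, 0])

    def test_nonpositive_ct_names_cell_and_gene(self):
        ct = scqpcr.CtMatrix(pd.DataFrame({"KLRB1": [20.0, -1.0]},
                                          index=["c0", "c1"]))
        with pytest.raises(ValueError, match=r"c1.*KLRB1"):
            scqpcr.compute_log2ex(ct)

    def test_expressed_iff_positive_log2ex(self):
        rng = np.random.default_rng(0)
        ct = ct_matrix({"g": rng.uniform(10, 30, size=50)})
        out = scqpcr.compute_log2ex(ct)
        assert (out.expressed == (out.values > 0)).all().all()

    @given(st.floats(5.0, 23.5), st.floats(0.1, 6.0))
    def test_monotone_decreasing_in_ct(self, ct_value, delta):
        lower = scqpcr.compute_log2ex(ct_matrix({"g": [ct_value]}))
        higher = scqpcr.compute_log2ex(ct_matrix({"g": [ct_value + delta]}))
        assert lower.values.iloc[0, 0] >= higher.values.iloc[0, 0]

    def test_raising_lod_only_adds_expressed_cells(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 30, size=200)
        low = scqpcr.compute_log2ex(
            ct_matrix({"g": vals}, lod=pd.Series({"g": 20.0})))
        high = scqpcr.compute_log2ex(
            ct_matrix({"g": vals}, lod=pd.Series({"g": 26.0})))
        assert high.expressed["g"].sum() >= low.expressed["g"].sum()
        assert (high.expressed["g"] | ~low.expressed["g"]).all()


class TestAdjustLod:
    def test_unimodal_gene_keeps_default(self):
        rng = np.random.default_rng(2)
        ct = ct_matrix({"g": rng.normal(15, 1.0, size=200).clip(5, 23)})
        assert scqpcr.adjust_lod(ct)["g"] == 24.0

    def test_empty_gene_keeps_default(self):
        ct = ct_matrix({"g": [np.nan] * 30})
        assert scqpcr.adjust_lod(ct)["g"] == 24.0

    def test_too_few_cells_keeps_default(self):
        rng = np.random.default_rng(3)
        ct = ct_matrix({"g": list(rng.normal(14, 1, 10))
                        + [np.nan] * 30})
        assert scqpcr.adjust_lod(ct)["g"] == 24.0

    def test_bimodal_valley_matches_brute_force(self):
        # expressing mode near Ct 14, noise mode near Ct 23
        rng = np.random.default_rng(4)
        cts = np.concatenate([rng.normal(14, 1.0, 300),
                              rng.normal(23, 0.8, 150)])
        ct = ct_matrix({"g": cts})
        lod = scqpcr.adjust_lod(ct)["g"]
        # independent oracle: exhaustive minimum of the smoothed histogram
        # between the two modes
        edges = np.arange(np.floor(cts.min()), np.ceil(cts.max()) + 0.5, 0.5)
        counts, edges = np.histogram(cts, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        smooth = gaussian_filter1d(counts.astype(float), 2.0)
        window = (centers > 15) & (centers < 22)
        oracle = centers[window][np.argmin(smooth[window])]
        assert lod == pytest.approx(oracle, abs=0.75)
        assert 17.0 < lod < 21.0

    def test_adjusted_lod_never_exceeds_default(self):
        rng = np.random.default_rng(5)
        cts = np.concatenate([rng.normal(20, 1.0, 300),
                              rng.normal(28, 0.8, 300)])
        ct = ct_matrix({"g": cts})
        assert scqpcr.adjust_lod(ct)["g"] <= 24.0

    def test_explicit_override_wins(self):
        rng = np.random.default_rng(6)
        ct = ct_matrix({"g": rng.normal(15, 1, 100)})
        assert scqpcr.adjust_lod(ct, overrides={"g": 21.5})["g"] == 21.5


class TestFilterMatrix:
    def _matrix(self, gene_counts: dict, n_cells=30, bad_cells=()):
        """Log2Ex matrix where gene g is expressed in gene_counts[g] cells."""
        vals = {}
        for g, k in gene_counts.items():
            vals[g] = [19.0] * k + [np.nan] * (n_cells - k)
        vals["B2M"] = [15.0] * n_cells
        vals["Spike1"] = [15.0] * n_cells
        df = pd.DataFrame(vals, index=[f"c{i}" for i in range(n_cells)])
        for c in bad_cells:
            df.loc[c, ["B2M", "Spike1"]] = np.nan
        return scqpcr.compute_log2ex(scqpcr.CtMatrix(df))

    def test_gene_in_nine_cells_removed_ten_retained(self):
        out = scqpcr.filter_matrix(self._matrix({"g9": 9, "g10": 10}))
        assert "g9" not in out.values.columns
        assert "g10" in out.values.columns
        assert out.filter_report["genes_removed"] == ["g9"]

    def test_cell_without_controls_removed(self):
        out = scqpcr.filter_matrix(
            self._matrix({"g": 20}, bad_cells=["c0"]))
        assert "c0" not in out.values.index
        assert out.filter_report["cells_removed"] == ["c0"]

    def test_controls_dropped_from_analysis_matrix(self):
        out = scqpcr.filter_matrix(self._matrix({"g": 20}))
        assert "B2M" not in out.values.columns
        assert "Spike1" not in out.values.columns

    def test_all_cells_removed_is_an_error(self):
        mat = self._matrix({"g": 5}, n_cells=5,
                           bad_cells=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="all cells removed"):
            scqpcr.filter_matrix(mat)

    def test_idempotent(self):
        once = scqpcr.filter_matrix(self._matrix({"g": 20, "h": 12}))
        twice = scqpcr.filter_matrix(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


def brute_force_ward(points: np.ndarray):
    """Independent agglomerative Ward oracle for a handful of points.

    Tracks cluster sizes/centroids and merges the pair with minimal
    increase in within-cluster sum of squares; returns merge heights in
    scipy convention (sqrt of 2x the ESS increase).
    """
    clusters = [(1, p.astype(float)) for p in points]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ni, ci = clusters[i]
                nj, cj = clusters[j]
                d2 = ((ci - cj) ** 2).sum()
                cost = (ni * nj) / (ni + nj) * d2
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        ni, ci = clusters[i]
        nj, cj = clusters[j]
        merged = (ni + nj, (ni * ci + nj * cj) / (ni + nj))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        heights.append(np.sqrt(2.0 * cost))
    return np.array(heights)


class TestClusterBinary:
    def _log2ex(self, arr, cells=None, genes=None):
        cells = cells or [f"c{i}" for i in range(arr.shape[0])]
        genes = genes or [f"g{j}" for j in range(arr.shape[1])]
        vals = pd.DataFrame(arr, index=cells, columns=genes)
        return scqpcr.Log2ExMatrix(vals, vals > 0)

    def test_identical_cells_merge_first_at_zero(self):
        arr = np.array([[5.0, 0.0], [5.0, 0.0], [0.0, 9.0], [1.0, 4.0]])
        res = scqpcr.cluster_binary(self._log2ex(arr))
        assert res.cell_linkage[0, 2] == 0.0
        assert set(res.cell_linkage[0, :2]) == {0.0, 1.0}

    def test_block_structure_bipartition(self):
        rng = np.random.default_rng(7)
        a = np.zeros((20, 6))
        a[:10, :3] = 6 + rng.normal(0, 0.3, (10, 3))
        a[10:, 3:] = 6 + rng.normal(0, 0.3, (10, 3))
        res = scqpcr.cluster_binary(self._log2ex(a))
        cut = res.cut_cells(2)
        first = cut[[f"c{i}" for i in range(10)]]
        second = cut[[f"c{i}" for i in range(10, 20)]]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_linkage_heights_match_brute_force_ward(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [5.0, 3.0]])
        res = scqpcr.cluster_binary(self._log2ex(pts))
        oracle = brute_force_ward(pts)
        assert np.allclose(np.sort(res.cell_linkage[:, 2]), np.sort(oracle))

    def test_row_permutation_gives_same_heights(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0, 8, size=(12, 5))
        m1 = self._log2ex(arr)
        perm = rng.permutation(12)
        m2 = scqpcr.Log2ExMatrix(m1.values.iloc[perm], m1.expressed.iloc[perm])
        r1, r2 = scqpcr.cluster_binary(m1), scqpcr.cluster_binary(m2)
        assert np.allclose(r1.cell_linkage[:, 2], r2.cell_linkage[:, 2])
        assert r1.cell_order == r2.cell_order


class TestExpressingFraction:
    def test_fractions(self):
        vals = pd.DataFrame({"g": [3.0] * 13 + [0.0] * 39},
                            index=[f"c{i}" for i in range(52)])
        mat = scqpcr.Log2ExMatrix(vals, vals > 0)
        labels = pd.Series("S", index=vals.index)
        out = scqpcr.expressing_fraction(mat, labels)
        assert out.loc["S", "g"] == pytest.approx(0.25)

    def test_all_and_none(self):
        vals = pd.DataFrame({"on": [2.0, 3.0], "off": [0.0, 0.0]},
                            index=["c0", "c1"])
        mat = scqpcr.Log2ExMatrix(vals, vals > 0)
        out = scqpcr.expressing_fraction(
            mat, pd.Series(["S", "S"], index=vals.index))
        assert out.loc["S", "on"] == 1.0
        assert out.loc["S", "off"] == 0.0

    def test_unlabeled_cells_error(self):
        vals = pd.DataFrame({"g": [1.0, 2.0]}, index=["c0", "c1"])
        mat = scqpcr.Log2ExMatrix(vals, vals > 0)
        with pytest.raises(ValueError, match="c1"):
            scqpcr.expressing_fraction(mat, pd.Series({"c0": "S"}))


class TestCtMatrixIO:
    def test_sentinels_normalized(self, tmp_path):
        path = tmp_path / "ct.tsv"
        path.write_text("cell\tg1\tg2\nc0\t20.5\t999\nc1\tNA\t\n")
        ct = scqpcr.CtMatrix.from_tsv(path)
        assert ct.values.loc["c0", "g1"] == 20.5
        assert np.isnan(ct.values.loc["c0", "g2"])
        assert np.isnan(ct.values.loc["c1", "g1"])
        assert np.isnan(ct.values.loc["c1", "g2"])


class TestSynthCtIntegration:
    def test_fraction_one_always_below_lod(self):
        prof = pd.DataFrame({"g": [1.0]}, index=["S"])
        ct = synth.gen_ct_matrix(prof, n_cells=50, seed=1,
                                 failed_control_frac=0.0)
        assert (ct.values["g"] < ct.lod["g"]).all()

    def test_fraction_zero_never_below_lod(self):
        prof = pd.DataFrame({"g": [0.0]}, index=["S"])
        ct = synth.gen_ct_matrix(prof, n_cells=50, seed=2,
                                 failed_control_frac=0.0)
        below = ct.values["g"].dropna() < ct.lod["g"]
        assert not below.any()

    def test_expressing_count_within_three_se(self):
        prof = pd.DataFrame({"g": [0.5]}, index=["S"])
        ct = synth.gen_ct_matrix(prof, n_cells=400, seed=3,
                                 failed_control_frac=0.0)
        n_expr = int((ct.values["g"] < ct.lod["g"]).sum())
        se = np.sqrt(400 * 0.5 * 0.5)
        assert abs(n_expr - 200) <= 3 * se
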