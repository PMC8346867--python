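"""Expression operations: size factors, fold changes, induction calls,
the early-response statistic, and PCA coordinates."""
import numpy as np
import pandas as pd
import pytest

from p53sig.rnaseq import (
    DEFAULT_LFC_MIN,
    early_response_fraction,
    induction_calls,
    lfc,
    lfc_tables,
    module_mean_lfc,
    pca_coordinates,
    size_factors_median_of_ratios,
)
from p53sig.types import CountMatrix, SampleSheet


def cm(data, genes=None):
    genes = genes or [f"g{i}" for i in range(len(next(iter(data.values()))))]
    return CountMatrix(pd.DataFrame(data, index=genes))


def sheet_for(lines, tps=(0, 8, 24)):
    rows = []
    for line in lines:
        for tp in tps:
            rows.append(
                dict(
                    sample_id=f"RNA_{line}_{tp}h",
                    cell_line=line,
                    tumor_type=line[:2],
                    assay="RNA",
                    condition="mock" if tp == 0 else "tam",
                    timepoint_h=tp,
                    path="",
                )
            )
    return SampleSheet(pd.DataFrame(rows))


class TestSizeFactors:
    def test_identical_columns_unity(self):
        sf = size_factors_median_of_ratios(cm({"a": [3, 7, 9], "b": [3, 7, 9]}))
        assert sf["a"] == pytest.approx(1.0)
        assert sf["b"] == pytest.approx(1.0)

    def test_hand_example(self):
        # two genes, samples (2,2) and (8,8): geomeans 4 -> factors 0.5 and 2
        sf = size_factors_median_of_ratios(cm({"a": [2, 2], "b": [8, 8]}))
        assert sf["a"] == pytest.approx(0.5)
        assert sf["b"] == pytest.approx(2.0)

    def test_column_scaling_equivariance(self):
        """Scaling one column by c scales its factor by c relative to the
        others; the per-gene geometric-mean reference shifts every factor
        by the common constant c**(-1/n), which normalization cannot (and
        need not) distinguish."""
        rng = np.random.default_rng(2)
        n = 4
        counts = rng.integers(1, 400, size=(50, n))
        base = cm({f"s{j}": counts[:, j] for j in range(n)})
        scaled_counts = counts.copy()
        scaled_counts[:, 2] *= 3
        scaled = cm({f"s{j}": scaled_counts[:, j] for j in range(n)})
        sf0 = size_factors_median_of_ratios(base)
        sf1 = size_factors_median_of_ratios(scaled)
        common = 3.0 ** (-1.0 / n)
        assert sf1["s2"] == pytest.approx(3 * common * sf0["s2"])
        assert sf1["s0"] == pytest.approx(common * sf0["s0"])
        # relative equivariance is exact
        assert sf1["s2"] / sf1["s0"] == pytest.approx(3 * sf0["s2"] / sf0["s0"])

    def test_textbook_oracle(self):
        """Median-of-ratios recomputed independently in long form."""
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 500, size=(100, 5))
        counts[:10] = rng.integers(1, 500, size=(10, 5))  # ensure all-positive genes
        matrix = cm({f"s{j}": counts[:, j] for j in range(5)})
        sf = size_factors_median_of_ratios(matrix)
        pos = counts[(counts > 0).all(axis=1)]
        geo = np.exp(np.mean(np.log(pos), axis=1))
        for j in range(5):
            assert sf[f"s{j}"] == pytest.approx(np.median(pos[:, j] / geo), rel=1e-12)

    def test_pydeseq2_cross_check(self):
        """Independent implementation check. pydeseq2 medians log-ratios, we
        median linear ratios; with an odd number of all-positive genes the
        median element is unique, so the two agree exactly."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 800, size=(201, 6))
        matrix = cm({f"s{j}": counts[:, j] for j in range(6)})
        sf = size_factors_median_of_ratios(matrix)
        _, ref = pydeseq2.deseq2_norm(counts.T)  # samples x genes
        assert np.allclose([sf[f"s{j}"] for j in range(6)], ref, rtol=1e-10)

    def test_no_all_positive_gene(self):
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(cm({"a": [0, 5], "b": [5, 0]}))


class TestLfc:
    def test_identical_samples_zero(self):
        matrix = cm({"a": [10, 20], "b": [10, 20]})
        sf = {"a": 1.0, "b": 1.0}
        assert lfc(matrix, sf, "g0", "a", "b") == 0.0

    def test_exact_powers(self):
        matrix = cm({"a": [31], "b": [7]})
        sf = {"a": 1.0, "b": 1.0}
        assert lfc(matrix, sf, "g0", "a", "b") == pytest.approx(2.0)

    def test_antisymmetric(self):
        matrix = cm({"a": [123], "b": [45]})
        sf = {"a": 1.3, "b": 0.8}
        assert lfc(matrix, sf, "g0", "a", "b") == pytest.approx(
            -lfc(matrix, sf, "g0", "b", "a")
        )

    def test_invariant_under_sample_rescaling(self):
        """Multiplying one sample's counts by c is absorbed by its size
        factor: fold changes are exactly invariant (the geometric-mean
        reference shift is a common constant that cancels in the ratio
        when no pseudocount is added)."""
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 300, size=(60, 6))
        lines = ["LA1", "LA2"]
        sheet = sheet_for(lines)
        sample_ids = [f"RNA_{ln}_{tp}h" for ln in lines for tp in (0, 8, 24)]
        m1 = CountMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(60)], columns=sample_ids)
        )
        scaled = counts.copy()
        scaled[:, 3] *= 5
        m2 = CountMatrix(
            pd.DataFrame(scaled, index=[f"g{i}" for i in range(60)], columns=sample_ids)
        )
        t1 = lfc_tables(m1, size_factors_median_of_ratios(m1), sheet, pseudocount=0.0)
        t2 = lfc_tables(m2, size_factors_median_of_ratios(m2), sheet, pseudocount=0.0)
        for a, b in zip(t1, t2):
            assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


def lfc_frames(values_by_line):
    genes = [f"g{i}" for i in range(len(next(iter(values_by_line.values()))))]
    frame = pd.DataFrame(values_by_line, index=genes)
    full = {}
    for line in ("LA1", "LA2", "SA1", "SA2", "LY1", "LY2"):
        full[line] = frame[line] if line in frame else pd.Series(0.0, index=genes)
    return pd.DataFrame(full)


class TestInductionCalls:
    def call24(self, la1, la2, lfc_min=DEFAULT_LFC_MIN):
        table = lfc_frames({"LA1": [la1], "LA2": [la2]})
        expr = induction_calls(table * 0.0, table, lfc_min)
        return bool(expr.induced24.iloc[0]["LA"])

    def test_clear_induction(self):
        assert self.call24(1.0, 1.0)

    def test_sign_consistency_clause(self):
        assert not self.call24(2.0, -0.1)

    def test_threshold_arithmetic(self):
        assert not self.call24(0.6, 0.5)  # mean 0.55 < 0.585
        assert self.call24(0.7, 0.5)      # mean 0.60 >= 0.585

    def test_repression_mirror(self):
        table = lfc_frames({"LA1": [-1.0], "LA2": [-0.9]})
        expr = induction_calls(table * 0.0, table)
        assert bool(expr.repressed24.iloc[0]["LA"])
        assert not bool(expr.induced24.iloc[0]["LA"])

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        table = lfc_frames(
            {ln: rng.normal(0.6, 0.5, 40) for ln in ("LA1", "LA2", "SA1", "SA2",
                                                     "LY1", "LY2")}
        )
        counts = [
            induction_calls(table * 0.0, table, lfc_min=t).induced24.to_numpy().sum()
            for t in (0.3, 0.585, 1.0, 1.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestEarlyResponseFraction:
    def build(self, e0, e8, e24, lines=("LA1", "LA2")):
        data = {}
        for line in lines:
            data[f"RNA_{line}_0h"] = [e0]
            data[f"RNA_{line}_8h"] = [e8]
            data[f"RNA_{line}_24h"] = [e24]
        matrix = CountMatrix(pd.DataFrame(data, index=["g0"]))
        sf = {c: 1.0 for c in data}
        return matrix, sf, sheet_for(lines)

    def test_constructed_exact_ratio(self):
        matrix, sf, sheet = self.build(100, 112, 200)
        assert early_response_fraction(matrix, sf, sheet, ["g0"]) == pytest.approx(12.0)

    def test_no_early_change_zero(self):
        matrix, sf, sheet = self.build(100, 100, 200)
        assert early_response_fraction(matrix, sf, sheet, ["g0"]) == pytest.approx(0.0)

    def test_saturated_early_change_full(self):
        matrix, sf, sheet = self.build(100, 200, 200)
        assert early_response_fraction(matrix, sf, sheet, ["g0"]) == pytest.approx(100.0)

    def test_empty_gene_set(self):
        matrix, sf, sheet = self.build(100, 112, 200)
        with pytest.raises(ValueError):
            early_response_fraction(matrix, sf, sheet, ["missing"])


class TestModuleMeanLfc:
    def test_constant_module(self):
        table = lfc_frames({ln: [-1.0, -1.0] for ln in ("LA1", "LA2")})
        expr = induction_calls(table * 0.0, table)
        assert module_mean_lfc(expr, ["g0", "g1"], "LA") == pytest.approx(-1.0)

    def test_singleton(self):
        table = lfc_frames({"LA1": [0.4, 2.0], "LA2": [0.6, 1.0]})
        expr = induction_calls(table * 0.0, table)
        assert module_mean_lfc(expr, ["g1"], "LA") == pytest.approx(1.5)

    def test_empty_set_rejected(self):
        table = lfc_frames({"LA1": [0.0]})
        expr = induction_calls(table * 0.0, table)
        with pytest.raises(ValueError):
            module_mean_lfc(expr, [], "LA")


class TestPca:
    def test_identical_samples_degenerate(self):
        matrix = cm({"a": [10, 20, 30], "b": [10, 20, 30]})
        res = pca_coordinates(matrix, {"a": 1.0, "b": 1.0})
        assert res.degenerate
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_single_gene_difference_on_pc1(self):
        matrix = cm({"a": [10, 100], "b": [10, 100], "c": [10, 800]})
        res = pca_coordinates(matrix, {s: 1.0 for s in "abc"}, n_components=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert abs(res.coordinates.loc["c", "PC1"]) > abs(
            res.coordinates.loc["a", "PC1"]
        )

    def test_variance_fractions_shape(self):
        rng = np.random.default_rng(13)
        matrix = cm({f"s{j}": rng.integers(1, 500, 40) for j in range(5)})
        res = pca_coordinates(matrix, None, n_components=3)
        vf = res.variance_fraction
        assert vf.sum() <= 1.0 + 1e-9
        assert all(vf[i] >= vf[i + 1] - 1e-12 for i in range(len(vf) - 1))

    def test_too_few_samples(self):
        matrix = cm({"a": [1, 2]})
        with pytest.raises(ValueError):
            pca_coordinates(matrix, {"a": 1.0}, n_components=2)
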