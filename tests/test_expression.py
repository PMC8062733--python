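"""Normalization (incl. TMM vs edgeR), expression filter, ISG calls, fractions."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from ifnsynergy.errors import ValidationError
from ifnsynergy.expression import (
    call_isgs,
    filter_expressed,
    fold_change,
    induced_fraction,
    normalize,
    percent,
    tmm_factors,
)
from ifnsynergy.pipeline import rna_groups


def norm_of(counts, lengths=None, method="libsize"):
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    return normalize(counts, lengths, method=method)


class TestNormalize:
    def test_single_gene_cpm_is_one_million(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        norm = norm_of(counts)
        assert norm.cpm.loc["g", "s"] == pytest.approx(1e6)

    def test_kilobase_gene_rpkm_equals_cpm(self):
        counts = pd.DataFrame({"s": [10, 30]}, index=["g1", "g2"])
        norm = norm_of(counts, pd.Series([1000, 2000], index=["g1", "g2"]))
        assert norm.rpkm.loc["g1", "s"] == norm.cpm.loc["g1", "s"]
        assert norm.rpkm.loc["g2", "s"] == norm.cpm.loc["g2", "s"] / 2

    def test_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 3)), columns=list("abc"))
        norm = norm_of(counts)
        assert np.allclose(norm.cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_identical_columns_tmm_factors_one(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0, 0]})
        with pytest.raises(ValidationError):
            norm_of(counts)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_tmm_matches_edger(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 4)),
            index=[f"g{i}" for i in range(300)],
            columns=list("ABCD"),
        )
        counts["B"] = (counts["B"] * 2.5).astype(int)
        counts.iloc[:20, 2] *= 8
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f'x <- read.delim("{path}", row.names=1)\n'
            'cat(sprintf("%.8f ", calcNormFactors(as.matrix(x), method="TMM")))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(counts).to_numpy()
        assert np.allclose(ours, ref, atol=1e-6)


class TestFilterAndFold:
    def test_below_threshold_in_all_samples_excluded(self):
        counts = pd.DataFrame({"a": [1, 999], "b": [1, 999]}, index=["low", "high"])
        norm = norm_of(counts)  # CPM of 'low' is 1000 in every sample
        kept = filter_expressed(norm, cpm_threshold=2000)
        assert list(kept) == ["high"]

    def test_boundary_is_inclusive(self):
        # CPM (1.0, 2.0): retained because 'below 2 in all samples' means < 2
        cpm_like = pd.DataFrame({"a": [1.0, 999999.0], "b": [2.0, 999998.0]}, index=["g", "rest"])
        norm = norm_of(cpm_like)
        assert "g" in filter_expressed(norm, cpm_threshold=2.0)

    def test_zero_threshold_keeps_all(self, noisy_small):
        _, ds = noisy_small
        norm = normalize(ds.expression.counts, ds.expression.lengths)
        assert len(filter_expressed(norm, 0.0)) == len(norm.cpm)

    @pytest.mark.parametrize("stim,basal,expected", [(0, 0, 1.0), (3, 1, 2.0), (1, 3, 0.5)])
    def test_fold_change_pseudocount(self, stim, basal, expected):
        assert fold_change(stim, basal) == pytest.approx(expected)


class TestCallIsgs:
    def rpkm_frame(self):
        # g_flat identical across conditions, g_up planted 8-fold
        return pd.DataFrame(
            {
                "unstim_0U_0h_r1": [10.0, 5.0],
                "unstim_0U_0h_r2": [10.0, 5.0],
                "unstim_0U_0h_r3": [10.0, 5.0],
                "beta_10U_4h_r1": [10.0, 40.0],
                "beta_10U_4h_r2": [10.0, 40.0],
                "beta_10U_4h_r3": [10.0, 40.0],
            },
            index=["g_flat", "g_up"],
        )

    def groups(self, rpkm):
        g = rna_groups(rpkm.columns)
        return {"beta_high": g["beta_high"]}, g["unstim"]

    def test_flat_gene_not_isg(self):
        rpkm = self.rpkm_frame()
        stim, basal = self.groups(rpkm)
        out = call_isgs(rpkm, stim, basal)
        assert not out.loc["g_flat", "isg"]
        assert out.loc["g_flat", "max_fold"] == pytest.approx(1.0)

    def test_planted_fold_recovered_exactly(self):
        rpkm = self.rpkm_frame()
        stim, basal = self.groups(rpkm)
        out = call_isgs(rpkm, stim, basal)
        assert out.loc["g_up", "isg"]
        assert out.loc["g_up", "max_fold"] == pytest.approx(41 / 6)

    def test_too_few_replicates_instructs_fold_only(self):
        rpkm = self.rpkm_frame()[["unstim_0U_0h_r1", "beta_10U_4h_r1"]]
        with pytest.raises(ValidationError, match="fold_only"):
            call_isgs(rpkm, {"beta_high": ["beta_10U_4h_r1"]}, ["unstim_0U_0h_r1"])
        out = call_isgs(
            rpkm, {"beta_high": ["beta_10U_4h_r1"]}, ["unstim_0U_0h_r1"], fold_only=True
        )
        assert out.loc["g_up", "isg"] and not out.loc["g_flat", "isg"]

    def test_noiseless_truth_recovery(self, noiseless_small):
        _, ds = noiseless_small
        norm = normalize(ds.expression.counts, ds.expression.lengths)
        expressed = filter_expressed(norm)
        groups = rna_groups(ds.expression.counts.columns)
        out = call_isgs(norm.rpkm.loc[expressed], {"beta_high": groups["beta_high"]}, groups["unstim"])
        planted = set(ds.truth.genes.index[ds.truth.genes["is_isg"]])
        called = set(out.index[out["isg"]])
        assert called == planted

    def test_monotone_in_thresholds(self, noisy_small):
        _, ds = noisy_small
        norm = normalize(ds.expression.counts, ds.expression.lengths)
        groups = rna_groups(ds.expression.counts.columns)
        args = (norm.rpkm, {"beta_high": groups["beta_high"]}, groups["unstim"])
        base = call_isgs(*args, fdr=0.05, fold=2.0)["isg"]
        higher_fold = call_isgs(*args, fdr=0.05, fold=4.0)["isg"]
        lower_fdr = call_isgs(*args, fdr=0.01, fold=2.0)["isg"]
        assert not (higher_fold & ~base).any()
        assert not (lower_fdr & ~base).any()


class TestInducedFraction:
    def test_printed_percentage_arithmetic(self):
        assert percent(10, 238) == 4
        assert percent(262, 353) == 74
        assert percent(25, 45) == 56
        assert percent(10, 45) == 22

    def test_fraction_and_count(self):
        maxfc = pd.Series({"a": 3.0, "b": 1.5, "c": 2.5})
        frac, k, n = induced_fraction(["a", "b", "c"], maxfc)
        assert (k, n) == (2, 3)
        assert frac == pytest.approx(2 / 3)

    def test_all_constant_is_zero(self):
        maxfc = pd.Series({"a": 1.0, "b": 1.0})
        frac, k, _ = induced_fraction(["a", "b"], maxfc)
        assert (frac, k) == (0.0, 0)

    def test_threshold_one_on_induced_set_is_total(self):
        maxfc = pd.Series({"a": 1.2, "b": 9.0})
        frac, _, _ = induced_fraction(["a", "b"], maxfc, fold_threshold=1.0)
        assert frac == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            induced_fraction([], pd.Series(dtype=float))
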