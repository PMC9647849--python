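import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from tmtde.io import AbundanceMatrix
from tmtde.normalize import (combat_correct, filter_missing, log2_zscore,
                             median_scale, mp_normalize, normalize_pipeline)
from tmtde.qc import pca_batch_check
from tmtde.simulate import SimulationConfig, simulate_dataset

from conftest import make_annotation, make_matrix


def _raw_two_batches(values, groups_b1=("PSP", "HC"), groups_b2=("PSP", "HC")):
    ann = make_annotation({1: list(groups_b1), 2: list(groups_b2)})
    return make_matrix(values, ann, scale="raw")


class TestMpNormalize:
    def test_divides_by_batch_mp(self):
        # columns: PSP01 HC01 MP_b1 PSP02 HC02 MP_b2
        m = _raw_two_batches([[8.0, 2.0, 8.0, 2.0, 4.0, 2.0]])
        out = mp_normalize(m)
        assert out.scale == "mp_ratio"
        assert out.mp_ids == []
        np.testing.assert_allclose(out.data.to_numpy()[0], [1.0, 0.25, 1.0, 2.0])

    def test_missing_or_zero_mp_blanks_batch(self):
        m = _raw_two_batches([[8.0, 2.0, np.nan, 2.0, 4.0, 2.0],
                              [8.0, 2.0, 4.0, 2.0, 4.0, 0.0]])
        out = mp_normalize(m)
        row0, row1 = out.data.to_numpy()
        assert np.isnan(row0[:2]).all() and not np.isnan(row0[2:]).any()
        assert np.isnan(row1[2:]).all() and not np.isnan(row1[:2]).any()

    def test_scale_equivariant_per_batch(self):
        vals = np.random.default_rng(0).lognormal(3, 1, size=(5, 6))
        m = _raw_two_batches(vals)
        scaled = vals.copy()
        scaled[:, 3:] *= 37.0  # whole batch 2, MP included
        m2 = _raw_two_batches(scaled)
        pd.testing.assert_frame_equal(mp_normalize(m).data, mp_normalize(m2).data)

    def test_requires_raw_scale(self):
        m = _raw_two_batches(np.ones((2, 6)))
        out = mp_normalize(m)
        with pytest.raises(ValueError, match="requires scale"):
            mp_normalize(out)


class TestMedianScale:
    @pytest.mark.parametrize("row,expected", [
        ([0.5, 1.0, 2.0], [0.5, 1.0, 2.0]),
        ([2.0, 4.0, 8.0], [0.5, 1.0, 2.0]),
        ([3.0, 3.0, 3.0], [1.0, 1.0, 1.0]),
    ])
    def test_rows(self, row, expected):
        ann = make_annotation({1: ["PSP", "PD", "HC"]}, include_mp=False)
        m = make_matrix([row], ann, scale="mp_ratio")
        np.testing.assert_allclose(median_scale(m).data.to_numpy()[0], expected)

    def test_output_row_medians_are_one(self):
        rng = np.random.default_rng(1)
        ann = make_annotation({1: ["PSP", "PD", "HC", "QC"]}, include_mp=False)
        vals = rng.lognormal(0, 1, size=(20, 4))
        vals[3, 1] = np.nan
        m = make_matrix(vals, ann, scale="mp_ratio")
        out = median_scale(m)
        np.testing.assert_allclose(out.data.median(axis=1, skipna=True), 1.0)

    def test_all_missing_row_passes_through(self):
        ann = make_annotation({1: ["PSP", "HC"]}, include_mp=False)
        m = make_matrix([[np.nan, np.nan], [1.0, 2.0]], ann, scale="mp_ratio")
        out = median_scale(m)
        assert out.data.iloc[0].isna().all()


class TestLog2Zscore:
    def test_geometric_row(self):
        ann = make_annotation({1: ["PSP", "PD", "HC"]}, include_mp=False)
        m = make_matrix([[0.5, 1.0, 2.0]], ann, scale="median_ratio")
        np.testing.assert_allclose(log2_zscore(m).data.to_numpy()[0], [-1, 0, 1])

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        ann = make_annotation({1: ["PSP"] * 4 + ["HC"] * 4}, include_mp=False)
        m = make_matrix(rng.lognormal(0, 0.4, size=(30, 8)), ann, scale="median_ratio")
        out = log2_zscore(m).data
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_warns_and_zeroes(self):
        ann = make_annotation({1: ["PSP", "PD", "HC"]}, include_mp=False)
        m = make_matrix([[2.0, 2.0, 2.0]], ann, scale="median_ratio")
        with pytest.warns(UserWarning, match="constant"):
            out = log2_zscore(m)
        np.testing.assert_allclose(out.data.to_numpy()[0], 0.0)

    def test_nonpositive_becomes_missing_with_warning(self):
        ann = make_annotation({1: ["PSP", "PD", "HC"]}, include_mp=False)
        m = make_matrix([[0.0, 1.0, 2.0]], ann, scale="median_ratio")
        with pytest.warns(UserWarning, match="non-positive"):
            out = log2_zscore(m)
        assert np.isnan(out.data.iloc[0, 0])


class TestFilterMissing:
    def test_drops_rows_with_any_missing(self):
        ann = make_annotation({1: ["PSP", "HC"]}, include_mp=False)
        m = make_matrix([[1, 2], [np.nan, 2], [3, 4]], ann, scale="zscore")
        out = filter_missing(m)
        assert list(out.data.index) == ["P0000", "P0002"]

    def test_complete_matrix_unchanged(self):
        ann = make_annotation({1: ["PSP", "HC"]}, include_mp=False)
        m = make_matrix([[1, 2], [3, 4]], ann, scale="zscore")
        pd.testing.assert_frame_equal(filter_missing(m).data, m.data)

    def test_retained_equals_proteins_observed_in_all_batches(self):
        cfg = SimulationConfig(n_proteins=400, p_batch_dropout=0.1, seed=8)
        matrix, truth = simulate_dataset(cfg)
        out = filter_missing(mp_normalize(matrix))
        expected = truth.observed.all(axis=1)
        assert set(out.data.index) == set(expected.index[expected])


def _zmatrix_two_batches(G=400, n_per_batch=200, shift=1.0, seed=0,
                         group_effect=0.0, frac_de=0.0):
    """Direct z-scale construction: N(0,1) + additive batch shift, with an
    optional planted group effect for signal-preservation checks."""
    rng = np.random.default_rng(seed)
    half = n_per_batch // 2
    ann = make_annotation({1: ["PSP"] * half + ["HC"] * half,
                           2: ["PSP"] * half + ["HC"] * half}, include_mp=False)
    X = rng.normal(size=(G, 2 * n_per_batch))
    batch2 = (ann["batch"] == 2).to_numpy()
    X[:, batch2] += shift
    de = np.zeros(G, bool)
    if frac_de > 0:
        de = rng.random(G) < frac_de
        is_psp = (ann["group"] == "PSP").to_numpy()
        X[np.ix_(de, is_psp)] += group_effect
    return make_matrix(X, ann, scale="zscore"), de


class TestCombat:
    def test_single_batch_is_identity(self):
        ann = make_annotation({1: ["PSP"] * 4 + ["HC"] * 4}, include_mp=False)
        X = np.random.default_rng(5).normal(size=(30, 8))
        m = make_matrix(X, ann, scale="zscore")
        out, model = combat_correct(m)
        assert model is None
        np.testing.assert_allclose(out.data.to_numpy(), X, atol=1e-8)

    def test_additive_shift_removed(self):
        # large n per batch: the EB shrinkage residual scales as 1/sqrt(n)
        m, _ = _zmatrix_two_batches(G=300, n_per_batch=500, shift=1.0, seed=6)
        out, _ = combat_correct(m, preserve_groups=False)
        ann = m.annotation.set_index("sample_id")
        b1 = [s for s in out.data.columns if ann.loc[s, "batch"] == 1]
        b2 = [s for s in out.data.columns if ann.loc[s, "batch"] == 2]
        diff = (out.data[b1].mean(axis=1) - out.data[b2].mean(axis=1)).abs()
        assert diff.mean() < 0.05
        assert abs((out.data[b1].mean(axis=1) - out.data[b2].mean(axis=1)).mean()) < 0.01

    def test_preserve_groups_keeps_planted_signal(self):
        m, de = _zmatrix_two_batches(G=500, n_per_batch=60, shift=0.8, seed=7,
                                     group_effect=0.8, frac_de=0.3)
        ann = m.annotation.set_index("sample_id")
        psp = [s for s in m.data.columns if ann.loc[s, "group"] == "PSP"]
        hc = [s for s in m.data.columns if ann.loc[s, "group"] == "HC"]
        before = m.data[psp].mean(axis=1) - m.data[hc].mean(axis=1)
        out, _ = combat_correct(m, preserve_groups=True)
        after = out.data[psp].mean(axis=1) - out.data[hc].mean(axis=1)
        rel = ((after[de] - before[de]).abs() / before[de].abs()).mean()
        assert rel < 0.10

    def test_batch_with_single_sample_rejected(self):
        ann = make_annotation({1: ["PSP", "HC", "PSP"], 2: ["HC"]}, include_mp=False)
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 4)), ann, scale="zscore")
        with pytest.raises(ValueError, match="single sample"):
            combat_correct(m)

    def test_incomplete_matrix_rejected(self):
        ann = make_annotation({1: ["PSP", "HC"], 2: ["PSP", "HC"]}, include_mp=False)
        X = np.ones((3, 4))
        X[1, 2] = np.nan
        m = make_matrix(X, ann, scale="zscore")
        with pytest.raises(ValueError, match="complete"):
            combat_correct(m)

    def test_batch_eta2_decreases_through_pipeline(self):
        cfg = SimulationConfig(n_proteins=500, batch_scale_sd=0.3,
                               batch_shift_sd=0.5, frac_de=0.1, seed=13)
        matrix, _ = simulate_dataset(cfg)
        stages = normalize_pipeline(matrix)
        before = pca_batch_check(filter_missing(stages["zscore"])).batch_eta2
        after = pca_batch_check(stages["batch_corrected"]).batch_eta2
        assert after < before

    def test_matches_reference_eb_implementation(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript unavailable")
        m, _ = _zmatrix_two_batches(G=60, n_per_batch=12, shift=0.8, seed=42,
                                    group_effect=0.5, frac_de=0.3)
        ann = m.annotation
        x_path, meta_path, out_path = (tmp_path / f for f in
                                       ("X.tsv", "meta.tsv", "sva.tsv"))
        m.data.to_csv(x_path, sep="\t")
        ann[["sample_id", "group", "batch"]].to_csv(meta_path, sep="\t", index=False)
        rcode = f"""
        suppressMessages(library(sva))
        X <- as.matrix(read.delim("{x_path}", row.names=1, check.names=FALSE))
        meta <- read.delim("{meta_path}")
        mod <- model.matrix(~group, data=meta)
        out <- ComBat(dat=X, batch=meta$batch, mod=mod, par.prior=TRUE)
        write.table(out, "{out_path}", sep="\\t", quote=FALSE, col.names=NA)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ours, _ = combat_correct(m, preserve_groups=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        np.testing.assert_allclose(ours.data.to_numpy(), ref.to_numpy(), atol=1e-4)


def test_pipeline_scale_order_enforced():
    ann = make_annotation({1: ["PSP", "PD", "HC"]})
    m = make_matrix(np.abs(np.random.default_rng(3).normal(5, 1, size=(4, 4))), ann)
    with pytest.raises(ValueError, match="requires scale"):
        median_scale(m)          # raw -> median_ratio skips mp_ratio
    with pytest.raises(ValueError, match="requires scale"):
        log2_zscore(mp_normalize(m))  # mp_ratio -> zscore skips median_ratio
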