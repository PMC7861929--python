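import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecgstack.delineate import Fiducials
from ecgstack.features import (AMP_NAMES, FEATURE_NAMES, INTER_NAMES,
                               MORPH_NAMES, FeatureGroupSelection, Normalizer,
                               apply_imputer, build_feature_table, combine,
                               extract_features, fit_imputer)
from ecgstack.preprocess import BEAT_LEN, Beat

FS = 360.0


def _beat(r=1000, label="N", samples=None):
    if samples is None:
        samples = np.zeros(BEAT_LEN)
        samples[90] = 1.0  # R spike
    return Beat(samples=samples, label=label, source=("rec", r))


def _fid(r=1000, **kw):
    defaults = dict(p_on=r - 70, p_peak=r - 61, p_off=r - 52, qrs_on=r - 12,
                    qrs_off=r + 12, t_on=r + 60, t_peak=r + 104, t_off=r + 140)
    defaults.update(kw)
    return Fiducials(r_peak=r, **defaults)


class TestExtractFeatures:
    def test_rr_interval_one_second(self):
        vals = extract_features(_beat(r=360), _fid(r=360), prev_r=0, fs=FS)
        assert vals["rr_inter"] == pytest.approx(1.0)

    def test_qrs_len_definition(self):
        fid = _fid(qrs_on=1000 - 18, qrs_off=1000 + 18)  # 36 samples
        vals = extract_features(_beat(), fid, prev_r=640, fs=FS)
        assert vals["qrs_len"] == pytest.approx(0.1)

    def test_interval_definitions(self):
        vals = extract_features(_beat(), _fid(), prev_r=640, fs=FS)
        assert vals["p_len"] == pytest.approx((70 - 52) / FS)
        assert vals["pr_inter"] == pytest.approx((70 - 12) / FS)
        assert vals["st_seg"] == pytest.approx((60 - 12) / FS)
        assert vals["qt_inter"] == pytest.approx((140 + 12) / FS)

    def test_r_amp_is_beat_max(self):
        samples = np.zeros(BEAT_LEN)
        samples[90] = 1.23
        vals = extract_features(_beat(samples=samples), _fid(), prev_r=640, fs=FS)
        assert vals["r_amp"] == pytest.approx(1.23)

    def test_missing_fiducials_are_nan(self):
        fid = Fiducials(r_peak=1000, qrs_on=988, qrs_off=1012)
        vals = extract_features(_beat(), fid, prev_r=None, fs=FS)
        for name in ("p_len", "t_len", "rr_inter", "pr_inter", "st_seg",
                     "qt_inter", "t_amp"):
            assert np.isnan(vals[name])
        assert not np.isnan(vals["qrs_len"])

    def test_shift_equivariance(self):
        k = 777
        a = extract_features(_beat(r=1000), _fid(r=1000), prev_r=640, fs=FS)
        b = extract_features(_beat(r=1000 + k), _fid(r=1000 + k),
                             prev_r=640 + k, fs=FS)
        for name in FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], nan_ok=True)

    def test_mismatched_r(self):
        with pytest.raises(ValueError):
            extract_features(_beat(r=10), _fid(r=20), prev_r=None, fs=FS)


class TestCombine:
    def _table(self, n=5):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(n, len(FEATURE_NAMES))),
                          columns=list(FEATURE_NAMES))
        df["label"] = "N"
        return df

    def test_morph_only_235(self):
        sel = FeatureGroupSelection(use_morph=True, use_inter=False, use_amp=False)
        assert combine(self._table(), sel).shape[1] == 235

    def test_inter_only_7(self):
        sel = FeatureGroupSelection(use_morph=False, use_inter=True, use_amp=False)
        assert combine(self._table(), sel).shape[1] == 7

    def test_full_default_243(self):
        assert combine(self._table(), FeatureGroupSelection()).shape[1] == 243

    @pytest.mark.parametrize("m,i,a,expected", [
        (True, False, False, 235), (False, True, False, 7),
        (False, False, True, 1), (True, True, False, 242),
        (True, False, True, 236), (False, True, True, 8),
        (True, True, True, 243),
    ])
    def test_all_group_combinations(self, m, i, a, expected):
        sel = FeatureGroupSelection(use_morph=m, use_inter=i, use_amp=a)
        assert len(sel.columns()) == expected

    def test_empty_selection_rejected(self):
        sel = FeatureGroupSelection(use_morph=False, use_inter=False, use_amp=False)
        with pytest.raises(ValueError):
            sel.columns()

    def test_column_order_frozen(self):
        cols = FeatureGroupSelection().columns()
        assert cols[:235] == list(MORPH_NAMES)
        assert cols[235:242] == list(INTER_NAMES)
        assert cols[242] == "r_amp"


class TestNormalizer:
    def test_basic_scaling(self):
        X = np.array([[0.0], [5.0], [10.0]])
        out = Normalizer().fit(X).transform(X)
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.full((4, 2), 3.0)
        out = Normalizer().fit(X).transform(X)
        np.testing.assert_array_equal(out, 0.0)

    def test_unfit_raises(self):
        with pytest.raises(RuntimeError):
            Normalizer().transform(np.ones((2, 2)))

    def test_test_values_clipped(self):
        train = np.array([[0.0], [1.0]])
        norm = Normalizer().fit(train)
        out = norm.transform(np.array([[-10.0], [10.0]]))
        np.testing.assert_allclose(out.ravel(), [-0.5, 1.5])

    @given(arrays(np.float64, (6, 3), elements=st.floats(-100, 100)))
    @settings(max_examples=50, deadline=None)
    def test_train_values_in_unit_interval(self, X):
        out = Normalizer().fit(X).transform(X)
        assert (out >= 0.0).all() and (out <= 1.0).all()

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(20, 4))
        base = Normalizer().fit(X).transform(X)
        X2 = X * np.array([2.0, 5.0, 0.5, 10.0]) + 7.0
        again = Normalizer().fit(X2).transform(X2)
        np.testing.assert_allclose(base, again, atol=1e-12)

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(10, 3))
        norm = Normalizer().fit(X)
        back = Normalizer.from_json(norm.to_json())
        np.testing.assert_allclose(back.transform(X), norm.transform(X))


class TestImputer:
    def test_median_fill(self):
        train = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        med = fit_imputer(train)
        np.testing.assert_allclose(med, [3.0, 5.0])
        filled = apply_imputer(med, np.array([[np.nan, np.nan]]))
        np.testing.assert_allclose(filled, [[3.0, 5.0]])

    def test_all_nan_column(self):
        med = fit_imputer(np.full((3, 1), np.nan))
        assert med[0] == 0.0


class TestBuildFeatureTable:
    def test_columns_and_rr_from_sequence(self):
        beats = [_beat(r=1000), _beat(r=1360)]
        fids = [_fid(r=1000), _fid(r=1360)]
        table = build_feature_table(beats, fids, FS)
        assert list(table.columns) == list(FEATURE_NAMES) + ["label"]
        assert np.isnan(table.loc[0, "rr_inter"])  # first beat: no prev
        assert table.loc[1, "rr_inter"] == pytest.approx(1.0)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            build_feature_table([_beat()], [], FS)
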