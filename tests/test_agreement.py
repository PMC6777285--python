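"""Agreement statistics against independent oracles.

The ICC implementation is checked against a brute-force two-way ANOVA
sum-of-squares decomposition written here (never sharing code with the
implementation) and against pingouin's ICC(A,1) on noisy matrices.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hrconcord import (
    MatchedPairs,
    bland_altman,
    compute_agreement,
    error_metrics,
    flag_outliers,
    icc_absolute_agreement,
    label_icc,
)


def icc_oracle(X):
    """Brute-force two-way ANOVA decomposition → ICC(2,1) absolute agreement."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_rows = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((X - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def pairs_from(crit, trck, pid="P001", phase="lab", tracker="w"):
    df = pd.DataFrame(
        {
            "epoch_start": pd.date_range("2018-04-02T09:00:00", periods=len(crit),
                                         freq="10s"),
            "criterion_bpm": np.asarray(crit, dtype=float),
            "tracker_bpm": np.asarray(trck, dtype=float),
        }
    )
    return MatchedPairs(pid, phase, tracker, df)


class TestICC:
    def test_perfect_agreement(self):
        p = pairs_from([80, 100, 120, 140], [80, 100, 120, 140])
        icc, ci = icc_absolute_agreement(p)
        assert icc == pytest.approx(1.0)

    def test_constant_offset_matrix_matches_oracle(self):
        # tracker = criterion + 20 on epochs (80, 100, 120, 140): ICC = 10/13
        p = pairs_from([80, 100, 120, 140], [100, 120, 140, 160])
        icc, _ = icc_absolute_agreement(p)
        assert icc == pytest.approx(10 / 13, abs=1e-12)
        assert icc == pytest.approx(
            icc_oracle(np.column_stack([p.criterion, p.tracker])), abs=1e-12
        )

    def test_alternating_deviation_matches_oracle(self):
        # deviations +5,−5,+5,−5 around (100,110,120,130): ICC = 32/35
        p = pairs_from([100, 110, 120, 130], [105, 105, 125, 125])
        icc, _ = icc_absolute_agreement(p)
        assert icc == pytest.approx(0.9142857142857141, abs=1e-12)
        assert icc == pytest.approx(
            icc_oracle(np.column_stack([p.criterion, p.tracker])), abs=1e-12
        )

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            X = rng.uniform(50, 180, size=(n, 2))
            icc, _ = icc_absolute_agreement(X)
            assert icc == pytest.approx(icc_oracle(X), abs=1e-10)

    def test_matches_pingouin_icc_a1(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        t = rng.uniform(60, 160, 40)
        X = np.column_stack([t, t]) + rng.normal(0, 5, (40, 2))
        icc, ci = icc_absolute_agreement(X)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": ["c", "t"] * 40,
                "ratings": X.ravel(),
            }
        )
        res = pg.intraclass_corr(df, "targets", "raters", "ratings")
        row = res[res["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        np.testing.assert_allclose(np.round(ci, 2), row["CI95"], atol=0.011)

    def test_degenerate_constant_input_returns_zero_with_warning(self):
        X = np.full((10, 2), 100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            icc, ci = icc_absolute_agreement(X)
        assert icc == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.array([[1.0, 2.0], [3.0, 4.0]]))

    @given(
        t=arrays(
            float,
            st.integers(5, 20),
            elements=st.floats(min_value=60, max_value=180, allow_nan=False),
            unique=True,
        ),
        eps=st.floats(min_value=0, max_value=2),
        c=st.floats(min_value=1, max_value=50),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shift_invariances(self, t, eps, c):
        """Common shifts leave ICC unchanged; one-column shifts lower it.

        Holds for agreeing paired data (shared signal plus small deviation):
        a constant added to one device is pure systematic disagreement.
        """
        if np.ptp(t) < 10:
            return  # not enough between-epoch signal
        X = np.column_stack([t, t + eps])
        base, _ = icc_absolute_agreement(X)
        both, _ = icc_absolute_agreement(X + c)
        assert both == pytest.approx(base, abs=1e-8)
        one = X.copy()
        one[:, 1] += c
        shifted, _ = icc_absolute_agreement(one)
        assert shifted < base + 1e-12
        assert shifted == pytest.approx(icc_oracle(one), abs=1e-10)


class TestErrorMetrics:
    def test_identical_streams(self):
        p = pairs_from([80, 100, 120], [80, 100, 120])
        em = error_metrics(p)
        assert em.mae_bpm == 0 and em.mape_percent == 0 and em.mean_diff_bpm == 0

    def test_symmetric_errors_forced_values(self):
        # (100→90) and (100→110): MAE 10 bpm, MAPE 10%, mean_diff 0
        em = error_metrics(pairs_from([100, 100], [90, 110]))
        assert em.mae_bpm == pytest.approx(10.0)
        assert em.mape_percent == pytest.approx(10.0)
        assert em.mean_diff_bpm == pytest.approx(0.0)

    def test_constant_offset_case(self):
        rng = np.random.default_rng(1)
        crit = rng.uniform(70, 150, 1000)
        em = error_metrics(pairs_from(crit, crit - 9.7))
        assert em.mean_diff_bpm == pytest.approx(-9.7, abs=1e-12)
        assert em.mae_bpm == pytest.approx(9.7, abs=1e-12)

    def test_mape_equals_mae_ratio_for_constant_criterion(self):
        crit = np.full(50, 120.0)
        trck = crit + np.linspace(-10, 10, 50)
        em = error_metrics(pairs_from(crit, trck))
        assert em.mape_percent == pytest.approx(em.mae_bpm / 120 * 100)


class TestBlandAltman:
    def test_constant_offset_collapses_loa(self):
        crit = np.linspace(80, 140, 20)
        ba = bland_altman(pairs_from(crit, crit + 3.4))
        assert ba.loa == pytest.approx((3.4, 3.4))

    def test_hand_computed_loa(self):
        # diffs {−2, 0, 2}: mean 0, sample SD 2, LoA ±3.92
        ba = bland_altman(pairs_from([100, 100, 100], [98, 100, 102]))
        assert ba.mean_diff_bpm == pytest.approx(0.0)
        assert ba.sd_diff_bpm == pytest.approx(2.0)
        assert ba.loa == pytest.approx((-3.92, 3.92))

    def test_loa_halfwidth_tracks_noise_sd(self):
        rng = np.random.default_rng(5)
        crit = rng.uniform(70, 150, 10_000)
        trck = crit + rng.normal(0, 5, 10_000)
        ba = bland_altman(pairs_from(crit, trck))
        half = (ba.loa[1] - ba.loa[0]) / 2
        assert half == pytest.approx(1.96 * 5, rel=0.03)

    def test_loa_cover_about_95pct_of_gaussian_diffs(self):
        rng = np.random.default_rng(8)
        crit = rng.uniform(70, 150, 10_000)
        diffs = rng.normal(-3, 4, 10_000)
        ba = bland_altman(pairs_from(crit, crit + diffs))
        inside = np.mean((diffs >= ba.loa[0]) & (diffs <= ba.loa[1]))
        assert 0.94 <= inside <= 0.96


class TestLabels:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.51, "moderate"),
            (0.83, "strong"),
            (0.50, "moderate"),
            (0.4999, "weak"),
            (0.73, "moderate"),
            (0.75, "strong"),
            (0.90, "very strong"),
            (0.89, "strong"),
            (-0.2, "weak"),
        ],
    )
    def test_band_mapping(self, icc, label):
        assert label_icc(icc) == label

    def test_summary_uses_report_precision(self):
        rng = np.random.default_rng(2)
        crit = rng.uniform(70, 150, 500)
        res = compute_agreement(pairs_from(crit, crit + rng.normal(-5, 6, 500)))
        s = res.summary()
        assert s["icc"] == round(res.icc, 2)
        assert isinstance(s["meets_validity_cutoff"], bool)


class TestOutlierScreen:
    def test_statuses(self):
        rng = np.random.default_rng(3)
        crit = rng.uniform(70, 150, 100)
        good = pairs_from(crit, crit + rng.normal(0, 3, 100), pid="good")
        anti = pairs_from(crit, 200 - crit, pid="anti")
        tiny = pairs_from([100, 110], [100, 110], pid="tiny")
        shuffled = pairs_from(crit, rng.permutation(crit), pid="shuffled")
        status = flag_outliers(
            {m.participant_id: m for m in (good, anti, tiny, shuffled)}
        )
        assert status["good"] == "ok"
        assert status["anti"] == "flagged"
        assert status["tiny"] == "not_evaluable"
        assert status["shuffled"] == "flagged"
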