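"""Confusion matrices, classification metrics, aggregation, z tests."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from hypnoval.epoch_metrics import (
    STAGE_ORDER,
    ConfusionMatrix4,
    aggregate_nights,
    compare_strata,
    confusion,
    night_metrics,
    pooled_confusion,
    two_proportion_z,
)
from hypnoval.errors import EmptyNightError
from hypnoval.hypnogram import AlignedPair


def _pair(ref, dev, mask=None):
    mask = mask if mask is not None else (True,) * len(ref)
    return AlignedPair("s", tuple(ref), tuple(dev), tuple(mask), 0.0)


class TestConfusion:
    def test_identity_is_diagonal(self, rng):
        seq = tuple(rng.choice(STAGE_ORDER, 50))
        cm = confusion(_pair(seq, seq))
        assert cm.counts.sum() == 50
        assert np.trace(cm.counts) == 50

    def test_enumeration(self):
        cm = confusion(_pair(("WAKE", "REM", "LIGHT", "DEEP"), ("WAKE", "LIGHT", "LIGHT", "LIGHT")))
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 0] = 1  # WAKE -> WAKE
        expected[1, 2] = 1  # REM -> LIGHT
        expected[2, 2] = 1  # LIGHT -> LIGHT
        expected[3, 2] = 1  # DEEP -> LIGHT
        assert (cm.counts == expected).all()

    def test_masked_epochs_never_counted(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 80))
            ref = rng.choice(STAGE_ORDER, n)
            dev = rng.choice(STAGE_ORDER, n)
            mask = rng.random(n) > 0.4
            if not mask.any():
                continue
            cm = confusion(_pair(ref, dev, tuple(bool(b) for b in mask)))
            brute = np.zeros((4, 4), dtype=int)
            for r, d, m in zip(ref, dev, mask):
                if m:
                    brute[STAGE_ORDER.index(r), STAGE_ORDER.index(d)] += 1
            assert (cm.counts == brute).all()

    def test_all_masked_raises(self):
        with pytest.raises(EmptyNightError):
            confusion(_pair(("WAKE",), ("WAKE",), (False,)))


class TestNightMetrics:
    def test_diagonal_perfect(self):
        m = night_metrics(ConfusionMatrix4(np.diag([10, 10, 10, 10])))
        assert m.kappa4 == m.accuracy4 == m.kappa2 == m.accuracy2 == 1.0
        assert all(v == 1.0 for v in m.se.values())
        assert all(v == 1.0 for v in m.sp.values())

    def test_sleep_wake_arithmetic(self):
        # 2x2 sleep-wake: TP_sleep=90, FN=10, FP=27, TN=73
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 73   # wake correctly wake
        counts[0, 2] = 27   # wake called light (sleep)
        counts[1, 1] = 90   # all sleep mass on REM for simplicity
        counts[1, 0] = 10
        m = night_metrics(ConfusionMatrix4(counts))
        assert m.se_sleep == pytest.approx(0.90)
        assert m.sp_sleep == pytest.approx(0.73)
        assert m.accuracy2 == pytest.approx(0.815)

    def test_zero_support_stage_undefined(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 50
        counts[2, 2] = 40
        counts[3, 2] = 10
        m = night_metrics(ConfusionMatrix4(counts))
        assert np.isnan(m.se["REM"])     # no reference REM
        assert not np.isnan(m.sp["REM"])  # specificity still defined

    def test_wake_sleep_duality_exact(self, rng):
        """se_wake == sp_sleep and sp_wake == se_sleep on any matrix."""
        for _ in range(200):
            counts = rng.integers(0, 30, size=(4, 4))
            if counts.sum() == 0:
                continue
            m = night_metrics(ConfusionMatrix4(counts))
            if not np.isnan(m.se["WAKE"]):
                assert m.se["WAKE"] == m.sp_sleep
            if not np.isnan(m.sp["WAKE"]):
                assert m.sp["WAKE"] == m.se_sleep

    def test_accuracy_is_prevalence_weighted_recall(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, size=(4, 4))
            n = counts.sum()
            if n == 0:
                continue
            m = night_metrics(ConfusionMatrix4(counts))
            acc = 0.0
            for s, i in zip(STAGE_ORDER, range(4)):
                support = counts[i, :].sum()
                if support:
                    acc += (support / n) * m.se[s]
            assert m.accuracy4 == pytest.approx(acc)

    def test_brute_force_se_sp_oracle(self, rng):
        """One-vs-rest Se/Sp against per-epoch counting on label sequences."""
        for _ in range(100):
            n = int(rng.integers(5, 60))
            ref = rng.choice(STAGE_ORDER, n)
            dev = rng.choice(STAGE_ORDER, n)
            m = night_metrics(confusion(_pair(ref, dev)))
            for s in STAGE_ORDER:
                tp = int(((ref == s) & (dev == s)).sum())
                fn = int(((ref == s) & (dev != s)).sum())
                fp = int(((ref != s) & (dev == s)).sum())
                tn = n - tp - fn - fp
                if tp + fn:
                    assert m.se[s] == pytest.approx(tp / (tp + fn))
                if tn + fp:
                    assert m.sp[s] == pytest.approx(tn / (tn + fp))


class TestAggregate:
    def _metric(self, value):
        return night_metrics(
            ConfusionMatrix4(
                np.array(
                    [[int(100 * value), 0, 100 - int(100 * value), 0],
                     [0, 100, 0, 0], [0, 0, 100, 0], [0, 0, 0, 100]]
                )
            )
        )

    def test_identical_nights_zero_sd(self):
        nights = [self._metric(0.8)] * 5
        out = aggregate_nights(nights)
        assert out.loc["accuracy4", "sd"] == 0
        assert out.loc["accuracy4", "ci95_low"] == out.loc["accuracy4", "ci95_high"]

    def test_hand_computed_mean_sd_ci(self):
        out = aggregate_nights([self._metric(0.5), self._metric(0.7)])
        row = out.loc["se_wake"]
        assert row["mean"] == pytest.approx(0.6)
        assert row["sd"] == pytest.approx(0.1414, abs=1e-4)
        assert row["ci95_high"] - row["mean"] == pytest.approx(1.96 * 0.14142 / np.sqrt(2), abs=1e-4)

    def test_undefined_nights_excluded_from_n(self):
        counts_no_rem = np.zeros((4, 4), dtype=int)
        counts_no_rem[0, 0] = counts_no_rem[2, 2] = counts_no_rem[3, 3] = 30
        nights = [self._metric(0.5), self._metric(0.7),
                  night_metrics(ConfusionMatrix4(counts_no_rem))]
        out = aggregate_nights(nights)
        assert out.loc["se_rem", "n_nights_used"] == 2
        assert out.loc["accuracy4", "n_nights_used"] == 3

    def test_bootstrap_ci_is_seeded(self):
        nights = [self._metric(v) for v in (0.4, 0.5, 0.6, 0.8, 0.9)]
        a = aggregate_nights(nights, ci_method="bootstrap", seed=1)
        b = aggregate_nights(nights, ci_method="bootstrap", seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestPooled:
    def test_single_matrix_identity(self):
        cm = ConfusionMatrix4(np.arange(16).reshape(4, 4))
        total, pct = pooled_confusion([cm])
        assert (total.counts == cm.counts).all()

    def test_rows_sum_to_100(self, rng):
        cms = [ConfusionMatrix4(rng.integers(0, 50, (4, 4))) for _ in range(5)]
        _, pct = pooled_confusion(cms)
        sums = pct.sum(axis=1)
        assert ((sums - 100).abs() <= 0.2).all()

    def test_order_invariant(self, rng):
        cms = [ConfusionMatrix4(rng.integers(0, 50, (4, 4))) for _ in range(4)]
        a, _ = pooled_confusion(cms)
        b, _ = pooled_confusion(cms[::-1])
        assert (a.counts == b.counts).all()


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p = two_proportion_z(30, 100, 30, 100)
        assert z == 0 and p == pytest.approx(1.0)

    def test_hand_computation(self):
        z, p = two_proportion_z(56, 100, 37, 100)
        assert z == pytest.approx(0.19 / np.sqrt(0.465 * 0.535 * 0.02), rel=1e-9)
        assert z == pytest.approx(2.693, abs=5e-3)

    def test_sign_antisymmetry(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(5, 200, 2)
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            z1, _ = two_proportion_z(x1, n1, x2, n2)
            z2, _ = two_proportion_z(x2, n2, x1, n1)
            assert z1 == pytest.approx(-z2)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(5, 200, 2)
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            z, p = two_proportion_z(x1, n1, x2, n2)
            z_sm, p_sm = proportions_ztest([x1, x2], [n1, n2])
            assert z == pytest.approx(z_sm)
            assert p == pytest.approx(p_sm)

    def test_degenerate_pooling(self):
        z, p = two_proportion_z(0, 10, 0, 10)
        assert np.isnan(z) and np.isnan(p)


class TestCompareStrata:
    def _pairs(self, rng, nights=4, n=200):
        out = []
        for _ in range(nights):
            ref = tuple(rng.choice(STAGE_ORDER, n))
            dev = tuple(s if rng.random() > 0.3 else rng.choice(STAGE_ORDER) for s in ref)
            out.append(AlignedPair("s", ref, dev, (True,) * n, 0.0))
        return out

    def test_identical_strata_zero_z(self, rng):
        pairs = self._pairs(rng)
        report = compare_strata(pairs, pairs)
        assert (report["z"].dropna().abs() < 1e-9).all()

    def test_epoch_partition(self, rng):
        pairs = self._pairs(rng)
        masks = [tuple(bool(b) for b in rng.random(p.n_epochs) > 0.5) for p in pairs]
        from hypnoval.consensus import stratify_epochs

        agree = [stratify_epochs(p, m)[0] for p, m in zip(pairs, masks)]
        disagree = [stratify_epochs(p, m)[1] for p, m in zip(pairs, masks)]
        report = compare_strata(agree, disagree)
        eps = report.attrs["epochs"]
        assert eps["agreement"]["n"] + eps["disagreement"]["n"] == sum(p.n_valid for p in pairs)
        assert eps["agreement"]["pct"] + eps["disagreement"]["pct"] == pytest.approx(100, abs=0.2)

    def test_worse_stratum_yields_positive_z(self, rng):
        """Extra device error injected on the 'disagreement' epochs drives z > 0."""
        good, bad = [], []
        for _ in range(5):
            n = 400
            ref = rng.choice(STAGE_ORDER, n)
            dev_good = np.where(rng.random(n) < 0.85, ref, rng.choice(STAGE_ORDER, n))
            dev_bad = np.where(rng.random(n) < 0.55, ref, rng.choice(STAGE_ORDER, n))
            good.append(AlignedPair("s", tuple(ref), tuple(dev_good), (True,) * n, 0.0))
            bad.append(AlignedPair("s", tuple(ref), tuple(dev_bad), (True,) * n, 0.0))
        report = compare_strata(good, bad)
        assert report.loc["accuracy4", "z"] > 0
        assert report.loc["accuracy2", "z"] > 0
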