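import math

import numpy as np
import pandas as pd
import pytest

from frnet.core import PatientRecord
from frnet.stats import (
    binomial_ci,
    bootstrap_auc_ci,
    auc_difference_test,
    events_to_model_frame,
    fit_feature_mixed_model,
    mann_whitney_auc,
    pca_global_measures,
    ranksum_holm,
    roc_auc,
)

from conftest import make_contact, make_event


def auc_pair_oracle(scores, labels):
    """Brute-force enumeration of concordant/tied pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [([3, 2], [1, 0], 1.0), ([1, 2, 3], [1, 2, 3], 0.5), ([3, 1], [2, 0], 0.75)],
    )
    def test_examples(self, pos, neg, expected):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert mann_whitney_auc(scores, labels) == pytest.approx(expected)
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_sweep_auc_equals_pair_statistic_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            auc_curve = roc_auc(scores, labels).auc
            auc_mw = mann_whitney_auc(scores, labels)
            assert abs(auc_curve - auc_mw) < 1e-12
            assert auc_mw == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        res = roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))
        assert math.isnan(res.auc)


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        a = bootstrap_auc_ci(scores, labels, n_boot=200, seed=7)
        b = bootstrap_auc_ci(scores, labels, n_boot=200, seed=7)
        assert a == b

    def test_perfect_separation_upper_bound_one(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = scores.astype(int)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=0)
        assert hi == pytest.approx(1.0)
        assert lo == pytest.approx(1.0)

    def test_difference_test_detects_better_marker(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 100 + [0] * 100)
        good = np.concatenate([rng.normal(2.0, 1, 100), rng.normal(0, 1, 100)])
        bad = rng.normal(0, 1, 200)
        p = auc_difference_test(good, bad, labels, n_boot=500, seed=3)
        assert p < 0.05
        same = auc_difference_test(bad, bad + 0.0, labels, n_boot=200, seed=4)
        assert same == pytest.approx(1.0)


class TestMixedModel:
    def _one_patient_frame(self):
        rng = np.random.default_rng(5)
        contacts = [make_contact(f"C{i}", region="temporal", is_soz=i < 3) for i in range(8)]
        events = []
        for c in contacts:
            for t in rng.uniform(0, 300, 40):
                f = math.exp(rng.normal(5.6 + (0.2 if c.is_soz else 0.0), 0.1))
                events.append(make_event(c.contact_id, float(t), peak_freq_hz=f))
        rec = PatientRecord(patient_id="P", contacts=contacts, events=events, duration_min=5.0)
        return events_to_model_frame([rec])

    def test_single_patient_falls_back_to_ols_oracle(self):
        import statsmodels.formula.api as smf

        frame = self._one_patient_frame()
        res = fit_feature_mixed_model(frame, "peak_freq_hz")
        assert res.used_ols_fallback
        frame = frame.assign(logy=np.log(frame["peak_freq_hz"]))
        ols = smf.ols("logy ~ soz + location", data=frame).fit()
        assert res.soz_coefficient == pytest.approx(float(ols.params["soz"]), abs=1e-10)
        assert res.intercept == pytest.approx(float(ols.params["Intercept"]), abs=1e-10)

    def test_requires_both_soz_classes(self):
        frame = self._one_patient_frame()
        with pytest.raises(ValueError):
            fit_feature_mixed_model(frame.loc[frame.soz == 1], "peak_freq_hz")


class TestRanksumHolm:
    def test_identical_groups_not_rejected(self):
        g = {"a": np.arange(10.0), "b": np.arange(10.0)}
        out = ranksum_holm(g, [("a", "b")])
        assert out["p_raw"].iloc[0] > 0.9
        assert not out["reject"].iloc[0]

    def test_exact_small_sample_p(self):
        g = {"a": np.array([1.0, 2, 3]), "b": np.array([10.0, 11, 12])}
        out = ranksum_holm(g, [("a", "b")])
        assert out["p_raw"].iloc[0] == pytest.approx(0.1)  # smallest attainable, 3v3

    def test_holm_step_down_rule_against_hand_oracle(self):
        def holm_oracle(raw):
            # hand application of the step-down rule: sort ascending, multiply
            # by (m - rank), enforce monotonicity, cap at 1
            m = len(raw)
            order = np.argsort(raw)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * raw[idx])
                adj[idx] = min(1.0, running)
            return adj

        assert np.allclose(holm_oracle(np.array([0.01, 0.04, 0.2])), [0.03, 0.08, 0.2])
        rng = np.random.default_rng(11)
        groups = {f"g{i}": rng.normal(0.2 * i, 1, 15) for i in range(4)}
        comps = [("g0", "g1"), ("g0", "g2"), ("g0", "g3"), ("g1", "g3")]
        out = ranksum_holm(groups, comps)
        assert np.allclose(out["p_holm"], holm_oracle(out["p_raw"].to_numpy()), atol=1e-12)

    def test_holm_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 12) for i in range(4)}
        comps = [("g0", "g1"), ("g0", "g2"), ("g0", "g3")]
        out = ranksum_holm(groups, comps)
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
        by_raw = out.sort_values("p_raw")
        assert by_raw["p_holm"].is_monotonic_increasing

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_holm({"a": np.array([]), "b": np.array([1.0])}, [("a", "b")])


class TestPCA:
    def _measures(self, x):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(len(x))],
                "mi_charpath": x[:, 0],
                "mi_mean_local_eff_nonsoz": x[:, 1],
                "mi_strength_diff": x[:, 2],
            }
        )

    def test_single_axis_explains_everything(self):
        t = np.linspace(-1, 1, 10)
        x = np.outer(t, [1.0, 2.0, -1.0])
        res = pca_global_measures(self._measures(x))
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_scores_are_uncorrelated_and_loadings_orthonormal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 3)) @ np.diag([3.0, 1.0, 0.3])
        res = pca_global_measures(self._measures(x))
        cov = np.cov(res.scores[["PC1", "PC2", "PC3"]].to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.allclose(off, 0, atol=1e-10)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-10)

    def test_planted_direction_recovered_within_5_degrees(self):
        rng = np.random.default_rng(8)
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        t = rng.normal(0, 3, 200)
        x = np.outer(t, axis) + rng.normal(0, 0.1, (200, 3))
        res = pca_global_measures(self._measures(x))
        # standardization rescales axes; the planted axis is symmetric so it survives
        angle = math.degrees(math.acos(abs(float(res.loadings[:, 0] @ axis))))
        assert angle < 5.0

    def test_missing_rows_excluded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 3))
        df = self._measures(x)
        df.loc[2, "mi_charpath"] = np.nan
        res = pca_global_measures(df)
        assert res.excluded_patients == ["p2"]
        assert len(res.scores) == 5


class TestBinomialCI:
    def test_boundaries(self):
        lo, hi = binomial_ci(10, 10)
        assert hi == 1.0 and lo == pytest.approx(0.025**0.1, abs=1e-6)
        lo0, hi0 = binomial_ci(0, 10)
        assert lo0 == 0.0 and hi0 == pytest.approx(1 - 0.025**0.1, abs=1e-4)

    def test_zero_of_ten_closed_form(self):
        lo, hi = binomial_ci(0, 10)
        assert (lo, hi) == pytest.approx((0.0, 0.3085), abs=2e-4)

    def test_symmetric_at_half(self):
        lo, hi = binomial_ci(5, 10)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 0)
        with pytest.raises(ValueError):
            binomial_ci(11, 10)


class TestAUCProperty:
    def test_mann_whitney_identity_hypothesis(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(
            pos=st.lists(st.integers(0, 5), min_size=1, max_size=12),
            neg=st.lists(st.integers(0, 5), min_size=1, max_size=12),
        )
        def check(pos, neg):
            scores = np.array(pos + neg, dtype=float)
            labels = np.array([1] * len(pos) + [0] * len(neg))
            assert abs(roc_auc(scores, labels).auc - mann_whitney_auc(scores, labels)) <= 1e-12
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                auc_pair_oracle(scores, labels), abs=1e-12
            )

        check()
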