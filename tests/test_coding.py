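import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adocnet import (
    CodingThresholds,
    ComparisonTable,
    RawRecords,
    ValidationError,
    code_attributes,
    robustness_sweep,
    sign_consistency_report,
)

def make_records(n, seed=0, texts_per_user=3):
    rng = np.random.default_rng(seed)
    users = pd.DataFrame(
        {
            "user_id": [f"u{k}" for k in range(n)],
            "gender": rng.choice(["male", "female"], n),
            "registration_time": rng.uniform(0, 1000, n).round(3),
        }
    )
    rows = []
    for k in range(n):
        for _ in range(texts_per_user):
            rows.append((f"u{k}", rng.normal(), int(rng.integers(1, 8))))
    texts = pd.DataFrame(rows, columns=["user_id", "sentiment", "topic"])
    return RawRecords(users, texts)


class TestCodeAttributes:
    def test_ten_users_default_tails(self):
        """q = 0.10 with 10 users: exactly one positive, one negative."""
        rec = make_records(10, seed=1)
        attrs = code_attributes(rec)
        pol = attrs.frame["emotion_polarity"]
        assert (pol == 2).sum() == 1 and (pol == 1).sum() == 1

    def test_modal_topic_tie_breaks_to_smallest(self):
        users = pd.DataFrame(
            {"user_id": ["a"], "gender": ["male"], "registration_time": [1.0]}
        )
        texts = pd.DataFrame(
            {
                "user_id": ["a"] * 6,
                "sentiment": [0.0] * 6,
                "topic": [1, 1, 1, 5, 5, 5],
            }
        )
        attrs = code_attributes(RawRecords(users, texts))
        assert attrs.frame.loc["a", "topic_preference"] == 1

    def test_reference_scale_counts(self):
        """N = 6,158 with f = 0.75, q = 0.10: 1,540 inexperienced, 616 per tail."""
        n = 6158
        assert math.ceil(0.25 * n) == 1540
        assert n - math.ceil(0.25 * n) == 4618
        assert math.ceil(0.10 * n) == 616
        rec = make_records(n, seed=3, texts_per_user=1)
        attrs = code_attributes(rec)
        exp = attrs.frame["experience"]
        pol = attrs.frame["emotion_polarity"]
        assert (exp == 0).sum() == 1540 and (exp == 1).sum() == 4618
        assert (pol == 2).sum() == 616 and (pol == 1).sum() == 616

    def test_gender_coding(self):
        rec = make_records(20, seed=4)
        attrs = code_attributes(rec)
        male = rec.users.set_index("user_id")["gender"] == "male"
        assert (attrs.frame["gender"] == male.astype(int)).all()

    def test_experience_follows_registration_order(self):
        """The earliest-registered users are the experienced ones."""
        rec = make_records(20, seed=5)
        attrs = code_attributes(rec, CodingThresholds(experienced_fraction=0.75))
        reg = rec.users.set_index("user_id")["registration_time"]
        coded = attrs.frame["experience"]
        newest = reg.sort_values().index[-math.ceil(0.25 * 20):]
        assert (coded.loc[newest] == 0).all()
        assert coded.sum() == 20 - math.ceil(0.25 * 20)

    def test_zero_text_user_rejected_by_name(self):
        rec = make_records(5, seed=6)
        texts = rec.texts[rec.texts["user_id"] != "u3"]
        with pytest.raises(ValidationError, match="u3"):
            code_attributes(RawRecords(rec.users, texts))

    def test_duplicate_user_rejected(self):
        rec = make_records(5, seed=7)
        users = pd.concat([rec.users, rec.users.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            RawRecords(users, rec.texts)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            CodingThresholds(experienced_fraction=1.2)
        with pytest.raises(ValidationError):
            CodingThresholds(polarity_fraction=0.5)

    @given(st.integers(5, 40), st.integers(0, 10**6))
    def test_tail_counts_exact(self, n, seed):
        rec = make_records(n, seed=seed)
        th = CodingThresholds()
        attrs = code_attributes(rec, th)
        pol = attrs.frame["emotion_polarity"]
        exp = attrs.frame["experience"]
        assert (pol == 2).sum() == math.ceil(0.10 * n)
        assert (pol == 1).sum() == math.ceil(0.10 * n)
        assert (exp == 0).sum() == math.ceil(0.25 * n)

    @given(st.integers(5, 25), st.integers(0, 10**6))
    def test_monotone_transform_invariance(self, n, seed):
        """Coding is rank-based in the user score: any strictly increasing
        transform of the scores leaves the polarity codes unchanged.  (One
        text per user so the user score IS the text score; with several
        texts only affine transforms commute with the mean.)"""
        rec = make_records(n, seed=seed, texts_per_user=1)
        attrs = code_attributes(rec)
        texts2 = rec.texts.copy()
        texts2["sentiment"] = np.exp(texts2["sentiment"] / 3.0)
        attrs2 = code_attributes(RawRecords(rec.users, texts2))
        assert attrs.frame.equals(attrs2.frame)

    def test_record_order_independence(self):
        rec = make_records(15, seed=9)
        shuffled = RawRecords(
            rec.users, rec.texts.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        assert code_attributes(rec).frame.equals(code_attributes(shuffled).frame)


# ---------------------------------------------------------------------------
# robustness sweep + flip detector
# ---------------------------------------------------------------------------

#: published robustness columns (baseline + gender-dropped + four recodings)
TABLE_ROBUSTNESS = {
    "term": [
        "mutual", "nodematch.gender",
        "nodematch.topic_preference.1", "nodematch.topic_preference.2",
        "nodematch.topic_preference.3", "nodematch.topic_preference.4",
        "nodematch.topic_preference.5", "nodematch.topic_preference.6",
        "nodematch.topic_preference.7", "nodeifactor.experience.1",
        "nodemix.emotion_polarity.2.2", "nodemix.emotion_polarity.1.1",
        "nodemix.emotion_polarity.2.1", "nodemix.emotion_polarity.1.2",
    ],
    "M0": [2.898, -0.005, 0.308, -0.295, -0.084, -0.021, 0.098, 0.094, 0.073,
           0.103, 0.413, -0.487, 0.534, -1.191],
    "M1": [3.174, np.nan, 0.364, -0.336, -0.093, -0.031, 0.067, 0.143, 0.107,
           0.123, 0.333, -0.488, 0.523, -1.168],
    "M2": [3.326, -0.013, 0.400, -0.350, -0.054, 0.003, 0.047, 0.124, 0.105,
           0.011, 0.403, -0.483, 0.494, -1.232],
    "M3": [3.202, -0.021, 0.347, -0.358, -0.150, 0.033, 0.100, 0.109, 0.084,
           0.126, 0.384, -0.594, 0.515, -1.246],
    "M4": [3.711, 0.003, 0.329, -0.319, -0.090, 0.014, 0.091, 0.209, 0.058,
           0.188, 0.371, -0.585, 0.562, -1.149],
    "M5": [3.389, 0.005, 0.450, -0.335, -0.051, -0.046, 0.067, 0.162, 0.108,
           0.155, 0.449, -0.493, 0.585, -1.083],
}
_STARRED = {
    "mutual", "nodematch.topic_preference.1", "nodematch.topic_preference.2",
    "nodeifactor.experience.1", "nodemix.emotion_polarity.2.2",
    "nodemix.emotion_polarity.1.1", "nodemix.emotion_polarity.2.1",
    "nodemix.emotion_polarity.1.2",
}


def reference_comparison() -> ComparisonTable:
    frame = pd.DataFrame(TABLE_ROBUSTNESS).set_index("term")
    stars = frame.copy().astype(object)
    for term in frame.index:
        for m in frame.columns:
            stars.loc[term, m] = "***" if term in _STARRED and np.isfinite(frame.loc[term, m]) else ""
    return ComparisonTable.from_values(frame, stars)


class TestSignConsistency:
    def test_fully_consistent_table_is_empty(self):
        est = pd.DataFrame({"M0": [1.0, -0.5], "M1": [1.2, -0.4]}, index=["a", "b"])
        stars = pd.DataFrame({"M0": ["***", ""], "M1": ["***", ""]}, index=["a", "b"])
        assert sign_consistency_report(ComparisonTable.from_values(est, stars)) == []

    def test_single_constructed_flip_detected(self):
        est = pd.DataFrame({"M0": [1.0, -0.5], "M1": [1.2, 0.4]}, index=["a", "b"])
        stars = pd.DataFrame({"M0": ["", ""], "M1": ["", ""]}, index=["a", "b"])
        flips = sign_consistency_report(ComparisonTable.from_values(est, stars))
        assert [(f.term, f.model, f.kind) for f in flips] == [("b", "M1", "sign")]

    def test_significance_class_change_detected(self):
        est = pd.DataFrame({"M0": [1.0], "M1": [0.9]}, index=["a"])
        stars = pd.DataFrame({"M0": ["***"], "M1": [""]}, index=["a"])
        flips = sign_consistency_report(ComparisonTable.from_values(est, stars))
        assert [(f.term, f.model, f.kind) for f in flips] == [("a", "M1", "significance")]

    def test_published_robustness_values(self):
        """The published columns flag gender (M4, M5) and the emotional-
        catharsis topic (the three recodings whose printed sign differs
        from the baseline)."""
        flips = sign_consistency_report(reference_comparison())
        by_term = {}
        for f in flips:
            by_term.setdefault(f.term, set()).add(f.model)
            assert f.kind == "sign"
        assert by_term == {
            "nodematch.gender": {"M4", "M5"},
            "nodematch.topic_preference.4": {"M2", "M3", "M4"},
        }

    def test_needs_two_columns(self):
        est = pd.DataFrame({"M0": [1.0]}, index=["a"])
        stars = pd.DataFrame({"M0": [""]}, index=["a"])
        with pytest.raises(ValidationError):
            sign_consistency_report(ComparisonTable.from_values(est, stars))


class TestRobustnessSweep:
    def test_sweep_shape_and_m1_lacks_gender(self, small_bundle):
        comp = robustness_sweep(
            small_bundle.records, small_bundle.network, seed=1, method="mple"
        )
        assert comp.models == ("M0", "M1", "M2", "M3", "M4", "M5")
        assert set(comp.terms()) == set(small_bundle.spec.names)
        assert np.isnan(comp.estimates.loc["nodematch.gender", "M1"])
        assert np.isfinite(comp.estimates.loc["nodematch.gender", "M0"])
        assert comp.meta["fractions"] == {
            "M0": 0.75, "M1": 0.75, "M2": 0.70, "M3": 0.73, "M4": 0.77, "M5": 0.80,
        }

    def test_identical_recoding_gives_identical_columns(self, small_bundle):
        """Fractions that move no user across the threshold refit identically."""
        n = len(small_bundle.attributes)
        # 0.75 and 0.76 both give ceil(0.25*60)=15 vs ceil(0.24*60)=15 inexperienced
        comp = robustness_sweep(
            small_bundle.records, small_bundle.network,
            fractions=(0.75, 0.755), seed=2, method="mple",
        )
        pd.testing.assert_series_equal(
            comp.estimates["M0"], comp.estimates["M2"], check_names=False
        )

    def test_baseline_fraction_required(self, small_bundle):
        with pytest.raises(ValidationError, match="0.75"):
            robustness_sweep(
                small_bundle.records, small_bundle.network, fractions=(0.7, 0.8)
            )
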