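"""Audiometric pattern analytics: slope, shoulder, Carhart, ROC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otomech.analysis import (
    InputError,
    carhart_correct,
    classify_slope,
    detect_shoulder,
    discriminant_statistic,
    roc_analysis,
)
from otomech.audiogram import Audiogram, CLINICAL_FREQUENCIES_HZ

F5 = np.asarray(CLINICAL_FREQUENCIES_HZ)


def ag(values, kind="simulated_abg"):
    return Audiogram(F5, np.asarray(values, float), kind=kind)


class TestSlopeRule:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((30, 30, 30, 30, 30), "none"),  # flat
            ((50, 50, 40, 30, 30), "up"),  # a=50, b=30, 40 between
            ((50, 50, 20, 30, 30), "none"),  # 1 kHz outside [b, a]
            ((15, 15, 25, 35, 35), "down"),
            ((45, 45, 45, 30, 40, ), "none"),  # a-b = 10, not > 10
            ((45, 45, 35, 30, 30), "up"),  # boundary-inclusive betweenness
        ],
    )
    def test_examples(self, values, expected):
        assert classify_slope(ag(values)) == expected

    @given(
        st.lists(
            st.integers(-20, 240).map(lambda k: k / 2.0), min_size=5, max_size=5
        ),
        st.integers(-80, 80).map(lambda k: k / 2.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_shift_invariance(self, values, shift):
        """Adding a constant to all five values never changes the class.

        Half-dB grids keep the means exactly representable, so the
        check exercises the rule rather than float rounding at the
        10-dB decision boundary.
        """
        assert classify_slope(ag(values)) == classify_slope(
            ag(np.asarray(values) + shift)
        )

    def test_missing_frequency_is_input_error(self):
        short = Audiogram(np.array([250.0, 500.0, 1000.0]), np.zeros(3))
        with pytest.raises(InputError):
            classify_slope(short)


class TestShoulder:
    @pytest.mark.parametrize(
        "v1000,expected",
        [(25.0, True), (35.0, False), (30.0, True)],  # 30 <= 40 - 10 boundary
    )
    def test_notch_depth_rule(self, v1000, expected):
        a = ag((40, 40, v1000, 40, 40))
        assert detect_shoulder(a, at=1000.0) is expected

    def test_boundary_frequency_rejected(self):
        with pytest.raises(InputError):
            detect_shoulder(ag((40, 40, 25, 40, 40)), at=250.0)


class TestCarhart:
    def test_published_notch_correction(self):
        """Raw means 25.0/35.2/26.3 dB HL at 1/2/4 kHz -> 25.65 at 2 kHz."""
        bc = ag((25.0, 25.0, 25.0, 35.2, 26.3), kind="bone_conduction")
        out = carhart_correct(bc)
        assert out.at(2000.0) == pytest.approx(25.65)
        # all other frequencies untouched
        for f in (250.0, 500.0, 1000.0, 4000.0):
            assert out.at(f) == bc.at(f)

    def test_idempotent(self):
        bc = ag((20, 20, 25.0, 35.2, 26.3), kind="bone_conduction")
        once = carhart_correct(bc)
        twice = carhart_correct(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_symmetric_bc_maps_to_flat(self):
        bc = ag((10, 10, 15.0, 40.0, 15.0), kind="bone_conduction")
        assert carhart_correct(bc).at(2000.0) == pytest.approx(15.0)

    def test_wrong_kind_rejected(self):
        with pytest.raises(InputError):
            carhart_correct(ag((1, 2, 3, 4, 5), kind="air_conduction"))


class TestDiscriminant:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((30, 30, 30, 30, 30), 0.0),
            ((40, 0, 45, 0, 10), 20.0),
            ((50, 0, 30, 0, 30), -10.0),
        ],
    )
    def test_examples(self, values, expected):
        assert discriminant_statistic(ag(values)) == pytest.approx(expected)

    def test_sustained_curve_scores_above_falling_curve(self):
        """A sigmoidal curve (high to 1 kHz) outranks an exponential
        decline at the same overall level - the basis of the 1-kHz rule
        separating attic fixation from stapes fixation."""
        f = F5
        sigmoid = 40.0 / (1 + np.exp((np.log2(f) - np.log2(1800.0)) * 3))
        exponential = 40.0 * (250.0 / f) ** 0.5
        exponential *= sigmoid.mean() / exponential.mean()  # matched level
        d_sig = discriminant_statistic(Audiogram(f, sigmoid))
        d_exp = discriminant_statistic(Audiogram(f, exponential))
        assert d_sig > d_exp


def _auc_pair_count(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_uninformative_scores(self):
        r = roc_analysis([5.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_pair_count_example(self):
        scores = [1, 2, 3, 4, 0, 1.5, 2.5]
        labels = [1, 1, 1, 1, 0, 0, 0]
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(_auc_pair_count(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_youden_tie_breaks_toward_sensitivity(self):
        # two cutoffs achieve J = 0.5; the lower one has sensitivity 1.0
        r = roc_analysis([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.sensitivity == 1.0

    def test_operating_points_monotone(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        r = roc_analysis(s, y)
        tprs = [p[1] for p in r.operating_points]
        fprs = [p[2] for p in r.operating_points]
        assert all(a >= b for a, b in zip(tprs, tprs[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))

    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=30),
        st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_auc_matches_pair_count_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        scores = [float(s) for s in scores]
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(_auc_pair_count(scores, labels))

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
        labels = (rng.random(200) < 0.4).astype(int)
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
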