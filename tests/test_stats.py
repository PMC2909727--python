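"""Group box summaries, Welch comparison, event correlation."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cytoscan import compare_groups, correlate_events, group_box_summary, size_group
from cytoscan.stats import GroupCompareConfig, event_intensity

from conftest import make_scores


def welch_oracle(a, b):
    """Hand-coded Welch t and Welch-Satterthwaite p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * sps.t.sf(abs(t), df)


class TestBoxSummary:
    def test_quartiles_match_oracle(self):
        scores = pd.DataFrame({"1p1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        box = group_box_summary(scores)
        assert (box.loc["1p1", ["q1", "median", "q3"]] == [2.0, 3.0, 4.0]).all()

    def test_loss_flag_when_box_below_zero(self):
        scores = pd.DataFrame({"1p1": [-3.0, -2.0, -1.0], "1q1": [-1.0, 0.0, 1.0]})
        box = group_box_summary(scores)
        assert box.loc["1p1", "flag"] == "loss"
        assert box.loc["1q1", "flag"] == "none"
        assert box.loc["1q1", "median"] == 0.0

    def test_quartile_ordering_invariant(self, rng):
        box = group_box_summary(make_scores(rng, n_samples=11))
        assert (box["q1"] <= box["median"]).all()
        assert (box["median"] <= box["q3"]).all()

    def test_too_few_members_rejected(self, rng):
        scores = make_scores(rng, n_samples=5)
        with pytest.raises(ValueError, match="2 samples"):
            group_box_summary(scores, members=["s00"])

    def test_merged_median_within_subgroup_envelope(self, rng):
        scores = make_scores(rng, n_samples=20)
        a, b = scores.index[:8], scores.index[8:]
        med_a = group_box_summary(scores, a)["median"]
        med_b = group_box_summary(scores, b)["median"]
        med_all = group_box_summary(scores)["median"]
        assert ((med_all >= np.minimum(med_a, med_b) - 1e-12)
                & (med_all <= np.maximum(med_a, med_b) + 1e-12)).all()


class TestCompareGroups:
    def test_hand_example_matches_oracle(self):
        scores = pd.DataFrame({"1p1": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]},
                              index=[f"s{i}" for i in range(6)])
        res = compare_groups(scores, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        t, p = welch_oracle([0, 1, 2], [10, 11, 12])
        assert res.loc["1p1", "t_stat"] == pytest.approx(t, abs=1e-12)
        assert res.loc["1p1", "p_value"] == pytest.approx(p, abs=1e-12)
        assert res.loc["1p1", "significant"]

    def test_identical_groups_null(self, rng):
        scores = make_scores(rng)
        res = compare_groups(scores, scores.index[:4], scores.index[:4])
        assert (res["t_stat"] == 0).all()
        assert not res["significant"].any()

    def test_zero_variance_equal_means_is_zero(self):
        scores = pd.DataFrame({"1p1": [1.0] * 8}, index=[f"s{i}" for i in range(8)])
        res = compare_groups(scores, scores.index[:4], scores.index[4:])
        assert res.loc["1p1", "t_stat"] == 0.0
        assert res.loc["1p1", "p_value"] == 1.0

    def test_antisymmetric_in_group_order(self, rng):
        scores = make_scores(rng, n_samples=12)
        a, b = scores.index[:5], scores.index[5:]
        ab = compare_groups(scores, a, b)
        ba = compare_groups(scores, b, a)
        np.testing.assert_allclose(ab["t_stat"], -ba["t_stat"], atol=0, rtol=0)

    def test_single_shifted_band_detected(self):
        rng = np.random.default_rng(2)
        scores = make_scores(rng, n_samples=20, bands=("1p2", "1p1", "1q1", "1q2"),
                             scale=1.0)
        a, b = scores.index[:10], scores.index[10:]
        scores.loc[b, "1q1"] += 5.0
        res = compare_groups(scores, a, b)
        assert res["significant"].sum() == 1
        assert res.loc["1q1", "significant"]


class TestCorrelation:
    def test_perfect_anticorrelation(self, rng):
        scores = make_scores(rng, n_samples=10, bands=("3p1", "5q1"))
        scores["5q1"] = -scores["3p1"]
        r, _ = correlate_events(scores, ["3p1"], ["5q1"], -1, 1)
        assert r == pytest.approx(1.0)  # -score vs -score: same orientation
        r2, _ = correlate_events(scores, ["3p1"], ["5q1"], 1, 1)
        assert r2 == pytest.approx(-1.0)

    def test_independent_intensities_near_zero(self):
        rng = np.random.default_rng(8)
        scores = make_scores(rng, n_samples=1000, bands=("3p1", "5q1"))
        r, p = correlate_events(scores, ["3p1"], ["5q1"], -1, 1)
        assert abs(r) < 0.1

    def test_hand_example_matches_pearson_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        scores = pd.DataFrame({"3p1": x, "5q1": y})
        r, p = correlate_events(scores, ["3p1"], ["5q1"], 1, 1)
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        scores = pd.DataFrame({"3p1": [1.0, 1.0, 1.0], "5q1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            correlate_events(scores, ["3p1"], ["5q1"], 1, 1)

    def test_too_few_samples_rejected(self, rng):
        scores = make_scores(rng, n_samples=2, bands=("3p1", "5q1"))
        with pytest.raises(ValueError, match="3 samples"):
            correlate_events(scores, ["3p1"], ["5q1"], 1, 1)


def test_size_groups():
    assert size_group(2.9) == "small"
    assert size_group(3.0) == "medium"
    assert size_group(7.0) == "medium"
    assert size_group(7.1) == "large"


def test_intensity_sign_orientation(rng):
    scores = make_scores(rng, n_samples=5, bands=("3p1", "3p2"))
    i = event_intensity(scores, ["3p1", "3p2"], -1)
    np.testing.assert_allclose(i, -scores[["3p1", "3p2"]].mean(axis=1))
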