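"""Rank-sum testing and ROC/Youden analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dceflow.features import FEATURE_COLUMNS
from dceflow.stats import group_comparison, roc_youden, wilcoxon_ranksum


def exact_ranksum_p(x, y):
    """Brute-force two-sided p: enumerate every assignment of pooled ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()  # mid-ranks
    nx = len(x)
    r_obs = ranks[:nx].sum()
    u_obs = r_obs - nx * (nx + 1) / 2
    mean_u = nx * len(y) / 2
    stat_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        r = ranks[list(comb)].sum()
        u = r - nx * (nx + 1) / 2
        if abs(u - mean_u) >= stat_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_force_roc(scores, labels, positive="non-OR"):
    """Exhaustive threshold/direction scan with the same tie-break rule."""
    scores = np.asarray(scores, float)
    pos = labels == positive
    n_pos, n_neg = pos.sum(), (~pos).sum()
    uniq = np.unique(scores)
    cuts = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = None
    for direction in (">=", "<="):
        for c in cuts:
            pred = scores >= c if direction == ">=" else scores <= c
            sens = (pred & pos).sum() / n_pos
            spec = (~pred & ~pos).sum() / n_neg
            key = (sens + spec - 1.0, sens)
            if best is None or key > best[0]:
                best = (key, c, direction, sens, spec)
    diff = scores[pos][:, None] - scores[~pos][None, :]
    auc = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (n_pos * n_neg)
    return dict(auc=auc, j=best[0][0], cutoff=best[1], direction=best[2],
                sensitivity=best[3], specificity=best[4])


class TestWilcoxonRanksum:
    def test_extreme_ordering_small_sample(self):
        # x entirely below y with n = (2, 2): p = 2 / C(4, 2) = 1/3
        res = wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
        assert res["exact"]
        assert res["p"] == pytest.approx(1 / 3)

    def test_identical_multisets_are_central(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_ranksum(x, list(x))
        assert res["u"] == pytest.approx(len(x) ** 2 / 2)
        assert res["p"] > 0.9

    def test_exact_matches_enumeration_5v5(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 5)
        res = wilcoxon_ranksum(x, y)
        assert res["exact"]
        assert res["p"] == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_ties_switch_to_corrected_normal_approximation(self):
        x = [1.0, 2.0, 2.0]
        y = [2.0, 3.0, 4.0]
        res = wilcoxon_ranksum(x, y)
        assert not res["exact"]
        assert 0.0 < res["p"] <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.3, 1.2, 11)
        p0 = wilcoxon_ranksum(x, y)["p"]
        for f in (np.exp, lambda v: v**3, lambda v: np.arctan(v) * 5 + 2):
            assert wilcoxon_ranksum(f(x), f(y))["p"] == pytest.approx(p0, rel=1e-12)


class TestROCYouden:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["OR"] * 3 + ["non-OR"] * 3)
        roc = roc_youden(scores, labels)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0
        assert roc.specificity == 1.0
        assert roc.youden_j == 1.0
        assert roc.direction == ">="
        assert 3.0 < roc.cutoff < 10.0

    def test_null_auc_is_half(self):
        rng = np.random.default_rng(77)
        scores = rng.normal(0, 1, 200)
        labels = np.where(rng.random(200) < 0.5, "OR", "non-OR")
        roc = roc_youden(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(6, 25)
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding makes ties
            labels = np.where(rng.random(n) < 0.5, "OR", "non-OR")
            if len(np.unique(labels)) < 2:
                continue
            got = roc_youden(scores, labels)
            ref = brute_force_roc(scores, labels)
            assert got.auc == pytest.approx(ref["auc"], abs=1e-12)
            assert got.youden_j == pytest.approx(ref["j"], abs=1e-12)
            assert got.sensitivity == pytest.approx(ref["sensitivity"], abs=1e-12)
            assert got.cutoff == pytest.approx(ref["cutoff"])
            assert got.direction == ref["direction"]

    def test_auc_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 40)
        labels = np.where(rng.random(40) < 0.4, "OR", "non-OR")
        a = roc_youden(scores, labels).auc
        b = roc_youden(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.arange(4.0), np.array(["OR"] * 4))


def _cohort_frame(rng, n_or=12, n_non=10, shift=None):
    rows = []
    for i in range(n_or + n_non):
        group = "OR" if i < n_or else "non-OR"
        row = {"lesion_id": f"L{i:03d}", "group": group}
        for tp in ("pre", "post", "delta"):
            for c in FEATURE_COLUMNS:
                v = rng.normal(0, 1)
                if shift and group == "OR" and (tp, c) in shift:
                    v += shift[(tp, c)]
                row[f"{tp}_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_table_has_24_rows(self):
        table = group_comparison(_cohort_frame(np.random.default_rng(0)))
        assert len(table) == 24
        assert set(table["timepoint"]) == {"pre", "post", "delta"}

    def test_null_false_positive_rate_near_alpha(self):
        # designed-zero effect: flagged fraction over many replicates ~ 5%
        rng = np.random.default_rng(42)
        flagged = total = 0
        for _ in range(150):
            table = group_comparison(_cohort_frame(rng))
            flagged += int(table["significant"].sum())
            total += len(table)
        rate = flagged / total
        assert 0.02 < rate < 0.08

    def test_designed_effect_recovered_with_direction(self):
        rng = np.random.default_rng(3)
        table = group_comparison(
            _cohort_frame(rng, shift={("post", "ifv_mean_mps"): 2.5})
        )
        row = table.set_index(["timepoint", "feature"]).loc[("post", "ifv_mean_mps")]
        assert row["significant"]
        assert row["or_mean"] > row["non_or_mean"]

    def test_identical_groups_are_not_significant(self):
        rng = np.random.default_rng(9)
        frame = _cohort_frame(rng, n_or=8, n_non=8)
        # copy OR values onto non-OR rows feature-wise
        cols = [c for c in frame.columns if c not in ("lesion_id", "group")]
        frame.loc[frame["group"] == "non-OR", cols] = (
            frame.loc[frame["group"] == "OR", cols].to_numpy()
        )
        table = group_comparison(frame)
        assert (table["p"] > 0.9).all()

    def test_missing_feature_columns_named_in_error(self):
        frame = _cohort_frame(np.random.default_rng(0)).drop(
            columns=["delta_ifv_kurt"])
        with pytest.raises(ValueError, match="delta_ifv_kurt"):
            group_comparison(frame)

    def test_bh_correction_flag_adds_adjusted_column(self):
        table = group_comparison(_cohort_frame(np.random.default_rng(1)),
                                 bh_correction=True)
        assert "p_adjusted" in table.columns
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
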