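"""ANOVA, Newman-Keuls, ROC/AUROC, cutoffs and the study comparison table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octfractal import (
    GroupData,
    anova_oneway,
    auroc,
    auroc_se,
    binormal_auroc,
    compare_layers,
    cutoff_mean_minus_2sd,
    newman_keuls,
    roc_curve,
    select_cutoff,
)
from octfractal.layers import LAYERS
from octfractal.oct_io import feature_column


def exact_moments(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """Sample with exactly the requested mean and sample SD (ddof=1)."""
    z = np.random.default_rng(seed).standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def brute_force_auroc(controls, cases, direction="low") -> float:
    """Pair-count oracle: concordant pairs + half ties over all pairs."""
    total = 0.0
    for c in cases:
        for h in controls:
            if (c < h and direction == "low") or (c > h and direction == "high"):
                total += 1.0
            elif c == h:
                total += 0.5
    return total / (len(cases) * len(controls))


class TestAnova:
    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        f, p = anova_oneway(GroupData("x", [a, b], ["g1", "g2"]))
        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p == pytest.approx(pt, rel=1e-12)

    def test_identical_constant_groups_give_zero_f(self):
        g = [np.full(5, 2.0)] * 3
        f, p = anova_oneway(GroupData("x", g, ["a", "b", "c"]))
        assert f == 0.0 and p == 1.0

    def test_matches_brute_force_sums_of_squares(self):
        groups = [
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
        ]
        f, _ = anova_oneway(GroupData("x", groups, list("abc")))
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_brute = (ss_between / 2) / (ss_within / 12)
        assert f == pytest.approx(f_brute, abs=1e-10)

    def test_zero_variance_separated_groups(self):
        f, p = anova_oneway(
            GroupData("x", [np.full(3, 0.0), np.full(3, 1.0)], ["a", "b"])
        )
        assert np.isinf(f) and p == 0.0


class TestNewmanKeuls:
    def test_two_group_decision_equals_pooled_t_test(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 12))
            b = rng.normal(rng.uniform(0, 1.5), 1, rng.integers(5, 12))
            table = newman_keuls(GroupData("x", [a, b], ["a", "b"]), alpha=0.05)
            _, p_t = sps.ttest_ind(a, b)
            assert bool(table.reject.iloc[0]) == (p_t < 0.05)
            assert table.p_value.iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_identical_means_never_rejected(self):
        g = [exact_moments(1.0, 0.5, 10, seed=s) for s in range(3)]
        table = newman_keuls(GroupData("x", g, list("abc")), alpha=0.05)
        assert not table.reject.any()

    def test_fixture_against_studentized_range_oracle(self):
        """Means 0/0/5, SD 1, n=20: outer pairs reject, 0-vs-0 does not.

        Frozen oracle values from an independent studentized-range
        implementation (R ptukey/qtukey): qcrit(0.95; 3, 57) = 3.4031891931,
        qcrit(0.95; 2, 57) = 2.8319138110.
        """
        groups = [
            exact_moments(0.0, 1.0, 20, seed=1),
            exact_moments(0.0, 1.0, 20, seed=2),
            exact_moments(5.0, 1.0, 20, seed=3),
        ]
        table = newman_keuls(GroupData("x", groups, ["a", "b", "c"]), alpha=0.05)
        table = table.set_index(["group_i", "group_j"])
        # q = diff / sqrt(MS_within / n) with MS_within = 1 exactly
        outer = table.loc[("a", "c")] if ("a", "c") in table.index else table.loc[("b", "c")]
        assert outer["q"] == pytest.approx(5 * np.sqrt(20), rel=1e-12)
        assert outer["q_crit"] == pytest.approx(3.4031891931, abs=1e-6)
        rejected = {
            idx for idx, row in table.iterrows() if row["reject"]
        }
        assert (("a", "b") not in rejected) and (("b", "a") not in rejected)
        assert len(rejected) == 2  # both 0-vs-5 pairs
        inner = [r for idx, r in table.iterrows() if r["span"] == 2 and r["reject"]]
        assert all(r["q_crit"] == pytest.approx(2.8319138110, abs=1e-6) for r in inner)

    def test_step_down_blocks_inner_pairs(self):
        # outer range non-significant -> inner pairs blocked even if large q
        groups = [
            exact_moments(0.0, 3.0, 4, seed=1),
            exact_moments(0.5, 3.0, 4, seed=2),
            exact_moments(1.0, 3.0, 4, seed=3),
        ]
        table = newman_keuls(GroupData("x", groups, list("abc")), alpha=0.05)
        assert not table.reject.any()

    def test_unequal_sizes_flagged_harmonic(self):
        groups = [exact_moments(0, 1, 5, 1), exact_moments(2, 1, 9, 2)]
        table = newman_keuls(GroupData("x", groups, ["a", "b"]), alpha=0.05)
        assert table.harmonic_n.all()


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 4, 5], [1, 2], direction="low") == 1.0

    def test_identical_distributions(self):
        x = [1, 2, 3, 4]
        assert auroc(x, x) == 0.5

    def test_tie_fixture_seven_ninths(self):
        """Controls {1,2,3}, cases {2,3,4}, low-is-disease: 2/9 + 2 half-ties."""
        a = auroc([1, 2, 3], [2, 3, 4], direction="low")
        assert a == pytest.approx(
            brute_force_auroc([1, 2, 3], [2, 3, 4], "low")
        )
        # fixed orientation: cases are HIGHER here, so AUROC is 2/9
        assert a == pytest.approx(2 / 9)
        # and the reversed orientation gives 7/9
        assert auroc([1, 2, 3], [2, 3, 4], "high") == pytest.approx(7 / 9)

    def test_matches_pair_count_oracle_on_random_samples(self, rng):
        for _ in range(50):
            controls = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            cases = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            for direction in ("low", "high"):
                assert auroc(controls, cases, direction) == pytest.approx(
                    brute_force_auroc(controls, cases, direction), abs=1e-12
                )

    def test_monotone_transform_invariance(self, rng):
        controls, cases = rng.normal(1, 1, 30), rng.normal(0, 1, 20)
        base = auroc(controls, cases)
        assert auroc(np.exp(controls), np.exp(cases)) == pytest.approx(base)
        assert auroc(controls**3, cases**3) == pytest.approx(base)

    def test_direction_flip_maps_a_to_one_minus_a(self, rng):
        controls, cases = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        assert auroc(controls, cases, "low") == pytest.approx(
            1 - auroc(controls, cases, "high")
        )

    def test_group_label_swap_symmetry(self, rng):
        controls, cases = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        assert auroc(cases, controls, "low") == pytest.approx(
            1 - auroc(controls, cases, "low")
        )


class TestRocCurve:
    def test_perfect_curve_passes_through_corner(self):
        df = roc_curve([3, 4, 5], [1, 2], direction="low")
        assert ((df.fpr == 0) & (df.tpr == 1)).any()
        assert df.fpr.is_monotonic_increasing
        assert df.tpr.iloc[-1] == 1.0 and df.fpr.iloc[-1] == 1.0

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        controls, cases = rng.normal(1, 1, 25), rng.normal(0.3, 1, 18)
        df = roc_curve(controls, cases, direction="low")
        area = np.trapezoid(df.tpr, df.fpr)
        assert area == pytest.approx(auroc(controls, cases, "low"), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([], [1.0])


class TestAurocSe:
    def test_perfect_auc_has_zero_se(self):
        assert auroc_se(1.0, 10, 12) == 0.0

    def test_formula_value(self):
        # independent evaluation of the Hanley-McNeil formula at A=0.5
        a, n1, n2 = 0.5, 10, 10
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        expect = np.sqrt(
            (a * (1 - a) + 9 * (q1 - a * a) + 9 * (q2 - a * a)) / 100
        )
        assert auroc_se(0.5, 10, 10) == pytest.approx(expect, abs=1e-15)
        # sqrt((0.25 + 9/12 + 9/12) / 100) evaluated by hand
        assert expect == pytest.approx(np.sqrt(0.0175), abs=1e-12)

    def test_se_shrinks_with_sample_size(self):
        ses = [auroc_se(0.8, n, n) for n in (5, 20, 80)]
        assert ses[0] > ses[1] > ses[2]


class TestSelectCutoff:
    def test_healthy_mean_minus_2sd_reproduces_166(self):
        healthy = exact_moments(1.68, 0.01, 74, seed=4)
        diseased = exact_moments(1.58, 0.05, 43, seed=5)
        res = select_cutoff(healthy, diseased, direction="low", rule="mean_minus_2sd")
        assert res.cutoff == pytest.approx(1.66, abs=1e-12)
        assert res.ci_low == pytest.approx(res.auroc - 1.96 * res.se)

    def test_plr_is_sens_over_one_minus_spec(self):
        res_plr = 0.98 / (1 - 0.88)
        assert res_plr == pytest.approx(8.1667, abs=1e-3)
        healthy = exact_moments(0.0, 1.0, 50, seed=6)
        diseased = exact_moments(-2.0, 1.0, 50, seed=7)
        res = select_cutoff(healthy, diseased, direction="low", rule="youden")
        if res.specificity < 1:
            assert res.plr == pytest.approx(
                res.sensitivity / (1 - res.specificity)
            )

    def test_perfect_specificity_flags_infinite_plr(self):
        res = select_cutoff([10, 11, 12], [1, 2, 3], direction="low", rule="youden")
        assert res.specificity == 1.0
        assert res.plr_infinite and np.isinf(res.plr)

    def test_zero_sd_degenerates_to_mean(self):
        res = select_cutoff([5.0, 5.0, 5.0], [1.0, 2.0, 3.0], rule="mean_minus_2sd")
        assert res.degenerate_sd
        assert res.cutoff == 5.0

    def test_high_direction_uses_plus_2sd(self):
        healthy = exact_moments(1.51, 0.01, 30, seed=8)
        diseased = exact_moments(1.56, 0.04, 30, seed=9)
        res = select_cutoff(healthy, diseased, direction="high", rule="mean_minus_2sd")
        assert res.cutoff == pytest.approx(1.53, abs=1e-12)
        assert cutoff_mean_minus_2sd(1.51, 0.01, "high") == pytest.approx(1.53)

    def test_youden_ties_break_toward_specificity(self):
        controls = np.array([2.0, 3.0, 4.0])
        cases = np.array([0.0, 1.0])
        res = select_cutoff(controls, cases, direction="low", rule="youden")
        # any cutoff in [1, 2) gives J = 1; the tie-break picks the most
        # specific threshold, which is the lowest case value boundary
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.cutoff == 1.0


class TestBinormal:
    def test_closed_form_against_simulation(self, rng):
        a_formula = binormal_auroc(1.68, 0.01, 1.58, 0.05)
        sims = []
        for _ in range(40):
            h = rng.normal(1.68, 0.01, 74)
            d = rng.normal(1.58, 0.05, 43)
            sims.append(auroc(h, d, "low"))
        assert np.mean(sims) == pytest.approx(a_formula, abs=0.01)
        assert a_formula == pytest.approx(
            sps.norm.cdf(0.10 / np.sqrt(0.01**2 + 0.05**2)), abs=1e-12
        )


class TestCompareLayers:
    @staticmethod
    def study_with_separation(seed=0, n_h=20, n_d=20):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_h + n_d):
            healthy = i < n_h
            row = {"eye_id": f"e{i:03d}", "group": "healthy" if healthy else "MDR"}
            for layer in LAYERS:
                row[feature_column("thickness", layer)] = rng.normal(40, 3)
                row[feature_column("reflectivity", layer)] = rng.normal(0.5, 0.05)
                if layer == "GCL+IPL":
                    row[feature_column("fd", layer)] = (
                        rng.normal(1.68, 0.01) if healthy else rng.normal(1.58, 0.05)
                    )
                else:
                    row[feature_column("fd", layer)] = rng.normal(1.7, 0.03)
            rows.append(row)
        return pd.DataFrame(rows)

    def test_planted_discriminator_ranks_highest(self):
        study = self.study_with_separation(seed=3)
        result = compare_layers(study)
        best = result.loc[result.auroc.idxmax()]
        assert (best["layer"], best["feature"]) == ("GCL+IPL", "fd")
        assert best["significant"]

    def test_missing_values_drop_only_that_row_eye(self):
        study = self.study_with_separation(seed=4)
        study.loc[0, feature_column("fd", "INL")] = np.nan
        result = compare_layers(study).set_index(["layer", "feature"])
        assert result.loc[("INL", "fd"), "n_healthy"] == 19
        assert result.loc[("INL", "fd"), "n_excluded"] == 1
        assert result.loc[("GCL+IPL", "fd"), "n_healthy"] == 20

    def test_identical_groups_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            rows = []
            for i in range(40):
                row = {"eye_id": f"e{i}", "group": "healthy" if i < 20 else "MDR"}
                for layer in LAYERS:
                    for feat in ("thickness", "fd", "reflectivity"):
                        row[feature_column(feat, layer)] = rng.normal()
                rows.append(row)
            result = compare_layers(pd.DataFrame(rows), alpha=0.001)
            hits += int(result["significant"].any())
        assert hits <= 1

    def test_single_group_rejected(self):
        study = self.study_with_separation().assign(group="healthy")
        with pytest.raises(ValueError, match="groups"):
            compare_layers(study)
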