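"""Tests for the in-silico experiment layer: splits, calibration, the
parameter grid, threshold curves, rule importance and the VAF/purity grid."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tmbsim as t
from tmbsim.experiment import RULE_FLAG_NAMES
from tmbsim.records import ValidationError


class TestSplitCohort:
    def test_exact_ratio_sizes(self):
        ids = [f"S{i}" for i in range(100)]
        train, val, test = t.split_cohort(ids, t.SplitSpec(base_seed=1), 0)
        assert (len(train), len(val), len(test)) == (80, 10, 10)

    def test_partition_properties(self):
        ids = [f"S{i}" for i in range(103)]
        spec = t.SplitSpec(base_seed=4)
        train, val, test = t.split_cohort(ids, spec, 2)
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))

    def test_deterministic_and_repetition_dependent(self):
        ids = [f"S{i}" for i in range(50)]
        spec = t.SplitSpec(base_seed=7)
        assert t.split_cohort(ids, spec, 3) == t.split_cohort(ids, spec, 3)
        assert t.split_cohort(ids, spec, 3) != t.split_cohort(ids, spec, 4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            t.split_cohort(["a"] * 5, t.SplitSpec(), 0)


class TestCalibrate:
    def test_noiseless_linear_recovery(self):
        """psTMB exactly 2x wesTMB recovers slope 0.5 with perfect metrics."""
        rng = np.random.default_rng(0)
        wes = rng.lognormal(1.0, 1.0, size=200)
        model, rep, metrics, degenerate = t.calibrate(2 * wes, wes, t.SplitSpec(base_seed=2))
        assert not degenerate
        assert model.slope == pytest.approx(0.5, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert metrics["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert metrics["rmsle"] == pytest.approx(0.0, abs=1e-9)
        assert metrics["discrete_accuracy"] == 1.0

    def test_attenuated_parameter_recovery(self):
        """With mild noise the selected slope approaches 1/a for ps = a*wes."""
        rng = np.random.default_rng(5)
        wes = rng.lognormal(1.0, 1.0, size=1000)
        ps = np.clip(0.8 * wes + rng.normal(0, 0.5, size=1000), 0, None)
        model, _, _, _ = t.calibrate(ps, wes, t.SplitSpec(base_seed=5))
        assert model.slope == pytest.approx(1.25, rel=0.05)

    def test_degenerate_flagged(self):
        wes = np.linspace(1, 20, 50)
        model, rep, metrics, degenerate = t.calibrate(np.zeros(50), wes, t.SplitSpec(base_seed=0))
        assert degenerate and model is None and np.isnan(metrics["rmsle"])

    def test_constant_fallback_predicts_train_mean(self):
        wes = np.linspace(1, 20, 50)
        model, _, metrics, degenerate = t.calibrate(
            np.zeros(50), wes, t.SplitSpec(base_seed=0), allow_constant=True
        )
        assert degenerate and model.slope == 0.0
        assert np.isfinite(metrics["discrete_accuracy"])


class TestEvaluateMethod:
    def test_expected_mode_invariant_to_profile(self, small_cohort, exome_panel):
        """After recalibration, expected-count metrics depend on the profile
        only through the (1 + rgbrp) scale factor, which the OLS slope
        absorbs — so they are identical across the recall >= precision grid."""
        _, _, samples, mutations = small_cohort
        spec = t.SplitSpec(base_seed=3)
        rule = t.ComputationRule()
        base = t.evaluate_method(exome_panel, rule, t.DetectionProfile(1, 1), samples, mutations, spec)
        for prof in (t.DetectionProfile(0.9, 0.5), t.DetectionProfile(0.7, 0.7)):
            res = t.evaluate_method(exome_panel, rule, prof, samples, mutations, spec)
            assert res.test_rmsle == pytest.approx(base.test_rmsle, abs=1e-9)
            assert res.test_discrete_accuracy == pytest.approx(base.test_discrete_accuracy)

    def test_stochastic_mode_reproducible(self, small_cohort, exome_panel):
        _, _, samples, mutations = small_cohort
        spec = t.SplitSpec(base_seed=3)
        kw = dict(count_mode="stochastic")
        a = t.evaluate_method(exome_panel, t.ComputationRule(), t.DetectionProfile(0.8, 0.6),
                              samples, mutations, spec, **kw)
        b = t.evaluate_method(exome_panel, t.ComputationRule(), t.DetectionProfile(0.8, 0.6),
                              samples, mutations, spec, **kw)
        assert a.test_rmsle == b.test_rmsle


class TestGrid:
    def test_combination_count_matches_enumeration(self):
        """Grid cardinality equals the brute-force product restricted to
        recall >= precision."""
        grid = t.GridSpec()
        vals = grid.recalls
        n_profiles = sum(1 for r in vals for p in vals if r >= p)
        expected = 2**6 * len(grid.vaf_cutoffs) * n_profiles
        assert grid.n_combinations() == expected == 64 * 5 * 21

    def test_single_combination_grid(self, small_cohort, exome_panel):
        _, _, samples, mutations = small_cohort
        grid = t.GridSpec(
            synonymous=(False,), nonsense=(True,), nonstop=(False,), splice_site=(False,),
            tss=(False,), hotspot_filter=(False,), vaf_cutoffs=(0.05,),
            recalls=(1.0,), precisions=(1.0,),
        )
        tab = t.run_grid([exome_panel], grid, samples, mutations, t.SplitSpec(base_seed=1))
        assert len(tab) == 1
        assert tab.iloc[0]["test_r_squared"] > 0.99

    def test_cache_rerun_identical(self, small_cohort, exome_panel):
        _, _, samples, mutations = small_cohort
        grid = t.GridSpec(
            synonymous=(False, True), nonsense=(True,), nonstop=(False,), splice_site=(False,),
            tss=(False,), hotspot_filter=(False,), vaf_cutoffs=(0.05,),
            recalls=(1.0,), precisions=(1.0,),
        )
        spec = t.SplitSpec(base_seed=1)
        cache: dict = {}
        first = t.run_grid([exome_panel], grid, samples, mutations, spec, cache=cache)
        second = t.run_grid([exome_panel], grid, samples, mutations, spec, cache=cache)
        pd.testing.assert_frame_equal(first, second)
        assert len(cache) == 2


class TestSaturationThresholds:
    def test_closed_form_exponential_curve(self):
        """acc(s) = 1 - exp(-s): the 95%-of-plateau size has a closed form."""
        sizes = np.linspace(0.05, 6.0, 120)
        scores = 1 - np.exp(-sizes)
        out = t.saturation_thresholds(sizes, scores)
        target = -np.log(1 - 0.95 * (1 - np.exp(-sizes[-1])))
        step = sizes[1] - sizes[0]
        assert abs(out["size_95"] - target) <= 2 * step

    def test_flat_curve_returns_smallest_size(self):
        sizes = np.linspace(1, 10, 20)
        out = t.saturation_thresholds(sizes, np.full(20, 0.9))
        assert out["size_95"] == sizes[0]

    def test_linear_curve_knee_matches_chord_scan(self):
        """On a straight line the chord distance is ~0 everywhere; the knee
        must agree with an independent brute-force scan over interior points."""
        sizes = np.linspace(1, 10, 30)
        scores = 0.05 * sizes + 0.1
        out = t.saturation_thresholds(sizes, scores)
        # brute-force: normalize, scan distance to chord
        from sklearn.isotonic import IsotonicRegression

        fitted = IsotonicRegression(increasing=True).fit_transform(sizes, scores)
        fitted[1:-1] = (fitted[:-2] + fitted[1:-1] + fitted[2:]) / 3
        x = (sizes - sizes[0]) / (sizes[-1] - sizes[0])
        y = (fitted - fitted[0]) / (fitted[-1] - fitted[0])
        brute = 1 + int(np.argmax((y - x)[1:-1]))
        assert out["knee_size"] == sizes[brute]

    def test_concave_knee_is_interior(self):
        sizes = np.linspace(0.1, 8, 40)
        out = t.saturation_thresholds(sizes, 1 - np.exp(-sizes))
        assert sizes[0] < out["knee_size"] < sizes[-1]

    def test_efficiency_thresholds_requires_sizes(self):
        df = pd.DataFrame(
            {
                "exonic_size_mb": [1, 2, 3],
                "test_discrete_accuracy": [0.8, 0.9, 0.95],
                "degenerate": False,
            }
        )
        with pytest.raises(ValidationError, match="10 distinct"):
            t.efficiency_thresholds(df)


def _importance_oracle(results, rule_columns):
    """Independent sort-and-slice re-derivation of the rule summary."""
    per_rule = {r: dict(at_least_one=0, always_in=0, always_out=0, unanimous=0) for r in rule_columns}
    n_used = 0
    for _, grp in results.groupby("panel_name"):
        n = len(grp)
        k = max(1, int(np.ceil(n * 0.05)))
        top_r2 = set(grp.sort_values("test_r_squared").index[-k:])
        top_acc = set(grp.sort_values("test_discrete_accuracy").index[-k:])
        low_rmsle = set(grp.sort_values("test_rmsle").index[:k])
        joint = top_r2 & top_acc & low_rmsle
        if not joint:
            continue
        n_used += 1
        sub = grp.loc[sorted(joint)]
        for r in rule_columns:
            inc = sub[r].astype(bool)
            per_rule[r]["at_least_one"] += int(inc.any())
            per_rule[r]["always_in"] += int(inc.all())
            per_rule[r]["always_out"] += int(~inc.any())
            per_rule[r]["unanimous"] += int(inc.all() or not inc.any())
    return per_rule, n_used


class TestRuleImportance:
    def _fixture(self, seed=31, n=100, panels=2):
        """Synthetic results: metrics share a latent quality, all distinct."""
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(panels):
            q = rng.normal(size=n)
            for i in range(n):
                rows.append(
                    {
                        "panel_name": f"P{p}",
                        "synonymous": bool(rng.integers(2)),
                        "nonsense": bool(rng.integers(2)),
                        "nonstop": bool(rng.integers(2)),
                        "splice_site": bool(rng.integers(2)),
                        "tss": bool(rng.integers(2)),
                        "hotspot_filter": bool(rng.integers(2)),
                        "test_r_squared": q[i] + rng.normal(0, 0.2),
                        "test_discrete_accuracy": q[i] + rng.normal(0, 0.2),
                        "test_rmsle": -q[i] + rng.normal(0, 0.2),
                        "degenerate": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_matches_sort_and_slice_oracle(self):
        results = self._fixture()
        got = t.rule_importance(results).set_index("rule")
        oracle, n_used = _importance_oracle(results, RULE_FLAG_NAMES)
        assert n_used > 0
        for rule in RULE_FLAG_NAMES:
            assert got.loc[rule, "at_least_one"] == oracle[rule]["at_least_one"]
            assert got.loc[rule, "always_in"] == oracle[rule]["always_in"]
            assert got.loc[rule, "always_out"] == oracle[rule]["always_out"]
            assert got.loc[rule, "matters_pct"] == pytest.approx(
                100 * oracle[rule]["unanimous"] / n_used
            )

    def test_unanimous_inclusion_counted(self):
        """A panel whose only top combo includes a rule lands in always_in."""
        results = self._fixture(seed=5, n=40, panels=1)
        results["synonymous"] = True
        results["test_discrete_accuracy"] = results["test_r_squared"]
        results["test_rmsle"] = -results["test_r_squared"]
        got = t.rule_importance(results).set_index("rule")
        assert got.loc["synonymous", "always_in"] == 1
        assert got.loc["synonymous", "always_out"] == 0
        assert got.loc["synonymous", "matters_pct"] == 100.0

    def test_split_rule_counts_nowhere(self):
        """A rule present in some-but-not-all top combos is not unanimous."""
        rng = np.random.default_rng(8)
        n = 100
        df = self._fixture(seed=8, n=n, panels=1)
        # force the joint top combos to disagree on 'tss'
        order = df.sort_values("test_r_squared").index
        df.loc[:, "test_discrete_accuracy"] = df["test_r_squared"]
        df.loc[:, "test_rmsle"] = -df["test_r_squared"]
        top = order[-5:]
        df.loc[top[:2], "tss"] = True
        df.loc[top[2:], "tss"] = False
        got = t.rule_importance(df).set_index("rule")
        assert got.loc["tss", "at_least_one"] == 1
        assert got.loc["tss", "always_in"] == 0
        assert got.loc["tss", "always_out"] == 0


class TestVafPurityGrid:
    def test_identity_transform_matches_baseline(self, small_cohort, exome_panel):
        """No rescaling and a 0 cutoff reproduce the plain evaluation."""
        _, _, samples, mutations = small_cohort
        spec = t.SplitSpec(base_seed=6)
        grid = t.vaf_purity_grid(
            samples, mutations, exome_panel, spec,
            target_purities=(None,), vaf_cutoffs=(0.0,),
        )
        rule0 = t.ComputationRule(vaf_cutoff=0.0)
        base = t.evaluate_method(
            exome_panel, rule0, t.DetectionProfile(1, 1), samples, mutations, spec
        )
        assert grid.iloc[0]["test_rmsle"] == pytest.approx(base.test_rmsle, abs=1e-12)
        assert grid.iloc[0]["test_discrete_accuracy"] == pytest.approx(
            base.test_discrete_accuracy
        )

    def test_dilution_removes_more_mutations_counting_oracle(self, small_cohort):
        """A 10% cutoff at 10% simulated purity removes strictly more calls
        than the same cutoff at 40% purity."""
        _, _, samples, mutations = small_cohort
        purity = samples.set_index("sample_id")["tumor_purity"]
        both = samples[samples["tumor_purity"] >= 0.4]["sample_id"]
        m = mutations[mutations["sample_id"].isin(both)]
        kept = {}
        for tp in (0.1, 0.4):
            scaled = m["vaf"] * np.minimum(1.0, tp / m["sample_id"].map(purity))
            kept[tp] = int((scaled >= 0.10).sum())
        assert kept[0.1] < kept[0.4]

    def test_low_purity_sample_skipped_with_warning(self, small_cohort, exome_panel):
        _, _, samples, mutations = small_cohort
        with pytest.warns(UserWarning, match="skipping"):
            grid = t.vaf_purity_grid(
                samples, mutations, exome_panel, t.SplitSpec(base_seed=6),
                target_purities=(0.4,), vaf_cutoffs=(0.05,),
            )
        assert grid.iloc[0]["n_samples"] < len(samples)
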