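import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mctarget import (
    GroupingLevel,
    bca_interval,
    bootstrap_replicates,
    enumerate_units,
    exhaustive_discordance,
    heterogeneity_report,
    jackknife_values,
    sample_pairs,
)
from mctarget.heterogeneity import Unit
from mctarget.synthetic_cohort import SyntheticConfig, ZeroInflatedBeta, generate_cohort
from conftest import cohort_from_scores


def _unit(calls, blocks=None, level=GroupingLevel.intra_tumoral):
    blocks = blocks or ["B1"] * len(calls)
    from mctarget.heterogeneity import _pair_counts

    cross = level is GroupingLevel.intra_patient_inter_tumoral
    n_pairs, n_disc = _pair_counts(calls, blocks, cross_block_only=cross)
    return Unit(("U",), level, tuple(calls), tuple(blocks), n_pairs, n_disc)


class TestEnumerateUnits:
    def test_two_blocks_give_one_inter_tumoral_unit(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"TROP2": 25.0}),
                ("P1", "lung", "B2", "S1", {"TROP2": 5.0}),
            ]
        )
        units = enumerate_units(cohort, GroupingLevel.intra_patient_inter_tumoral, "TROP2")
        assert len(units) == 1
        assert sorted(units[0].calls) == [False, True]
        assert units[0].n_pairs == 1 and units[0].n_discordant == 1

    def test_single_block_patient_excluded_at_inter_level(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", f"S{i}", {"TROP2": h})
                for i, h in enumerate([25.0, 5.0, 30.0])
            ]
        )
        assert enumerate_units(cohort, GroupingLevel.intra_patient_inter_tumoral, "TROP2") == []

    def test_block_of_three_samples_is_one_intra_unit(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", f"S{i}", {"TROP2": h})
                for i, h in enumerate([25.0, 5.0, 30.0])
            ]
        )
        units = enumerate_units(cohort, GroupingLevel.intra_tumoral, "TROP2")
        assert len(units) == 1
        assert units[0].n_pairs == 3 and units[0].n_discordant == 2

    def test_inter_level_counts_only_cross_block_pairs(self):
        # two blocks: [pos, pos] and [neg]; within-block pair is ineligible
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"TROP2": 50.0}),
                ("P1", "liver", "B1", "S2", {"TROP2": 60.0}),
                ("P1", "lung", "B2", "S1", {"TROP2": 0.0}),
            ]
        )
        (unit,) = enumerate_units(cohort, GroupingLevel.intra_patient_inter_tumoral, "TROP2")
        assert unit.n_pairs == 2 and unit.n_discordant == 2


class TestExhaustive:
    def test_single_discordant_pair(self):
        assert exhaustive_discordance([_unit([True, False])]) == 1.0

    def test_all_concordant_units(self):
        units = [_unit([True, True]), _unit([False, False])]
        assert exhaustive_discordance(units) == 0.0

    def test_two_of_three_pairs_discordant(self):
        assert exhaustive_discordance([_unit([True, False, True])]) == pytest.approx(2 / 3)

    def test_pooled_weighting_pools_pairs(self):
        units = [_unit([True, False]), _unit([True, True, True])]
        assert exhaustive_discordance(units, weighting="per_unit") == pytest.approx(0.5)
        assert exhaustive_discordance(units, weighting="pooled") == pytest.approx(1 / 4)


class TestSamplePairs:
    def test_single_fully_discordant_unit(self):
        out = sample_pairs([_unit([True, False])], n_pairs=200, seed=1)
        assert out.all()

    def test_seed_reproducibility(self):
        units = [_unit([True, False, True]), _unit([False, False, True])]
        a = sample_pairs(units, n_pairs=500, seed=42)
        b = sample_pairs(units, n_pairs=500, seed=42)
        assert (a == b).all()

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            sample_pairs([_unit([True, False])], n_pairs=10)

    def test_converges_to_exhaustive_oracle(self):
        units = [
            _unit([True, False, True]),
            _unit([False, False]),
            _unit([True, True, False, False]),
        ]
        exact = exhaustive_discordance(units)
        n = 100_000
        est = sample_pairs(units, n_pairs=n, seed=7).mean()
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(est - exact) <= 3 * se + 1e-12

    def test_monotone_threshold_preserving_transform_leaves_units_unchanged(self):
        scores = [0.0, 5.0, 25.0, 150.0, 19.0, 20.0]
        remap = lambda h: h / 2 if h < 20 else 100 + h / 2  # strictly monotone, keeps side of 20
        base = cohort_from_scores(
            [("P1", "liver", "B1", f"S{i}", {"TROP2": h}) for i, h in enumerate(scores)]
        )
        warped = cohort_from_scores(
            [("P1", "liver", "B1", f"S{i}", {"TROP2": remap(h)}) for i, h in enumerate(scores)]
        )
        u1 = enumerate_units(base, GroupingLevel.intra_tumoral, "TROP2")
        u2 = enumerate_units(warped, GroupingLevel.intra_tumoral, "TROP2")
        assert exhaustive_discordance(u1) == exhaustive_discordance(u2)


class TestBCa:
    def test_degenerate_distribution_collapses_to_point(self):
        lo, hi, degen = bca_interval(0.3, np.full(200, 0.3), np.array([0.3, 0.3]))
        assert (lo, hi, degen) == (0.3, 0.3, True)

    def test_symmetric_distribution_reduces_to_percentile(self):
        boots = np.concatenate([0.3 - np.linspace(0.01, 0.1, 100), 0.3 + np.linspace(0.01, 0.1, 100)])
        lo, hi, _ = bca_interval(0.3, boots, np.array([]))
        plo, phi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(plo) and hi == pytest.approx(phi)

    def test_matches_scipy_bca_on_a_mean(self):
        """Cross-check against the independent BCa in scipy.stats.bootstrap."""
        rng = np.random.default_rng(0)
        data = rng.beta(2, 5, 60)
        boots = np.array([rng.choice(data, data.size).mean() for _ in range(4000)])
        jk = np.array([np.delete(data, i).mean() for i in range(data.size)])
        lo, hi, _ = bca_interval(data.mean(), boots, jk, clip=(-np.inf, np.inf))
        ref = stats.bootstrap(
            (data,), np.mean, n_resamples=4000, method="BCa",
            random_state=np.random.default_rng(1), vectorized=False,
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.01)
        assert hi == pytest.approx(ref.high, abs=0.01)


class TestReport:
    def test_fully_concordant_cohort_estimates_zero_at_both_levels(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"TROP2": 100.0}),
                ("P1", "liver", "B1", "S2", {"TROP2": 150.0}),
                ("P1", "lung", "B2", "S1", {"TROP2": 120.0}),
                ("P2", "liver", "B1", "S1", {"TROP2": 0.0}),
                ("P2", "liver", "B1", "S2", {"TROP2": 5.0}),
                ("P2", "lung", "B2", "S1", {"TROP2": 10.0}),
            ]
        )
        rep = heterogeneity_report(cohort, ["TROP2"], seed=3, n_pairs=200, n_boot=100)
        assert (rep["estimate"] == 0.0).all()
        assert rep["degenerate"].all()

    def test_intra_zero_when_blocks_homogeneous_despite_between_block_differences(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"TROP2": 100.0}),
                ("P1", "liver", "B1", "S2", {"TROP2": 150.0}),
                ("P1", "lung", "B2", "S1", {"TROP2": 0.0}),
                ("P1", "lung", "B2", "S2", {"TROP2": 5.0}),
            ]
        )
        rep = heterogeneity_report(cohort, ["TROP2"], seed=3, n_pairs=500, n_boot=100)
        rep = rep.set_index("level")
        assert rep.loc["intra_tumoral", "estimate"] == 0.0
        assert rep.loc["intra_patient_inter_tumoral", "estimate"] == 1.0

    def test_unscored_marker_reported_not_evaluable(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"TROP2": 100.0}),
                ("P1", "liver", "B1", "S2", {"TROP2": 0.0}),
            ]
        )
        rep = heterogeneity_report(cohort, ["TROP2", "DLL3"], seed=3, n_pairs=100, n_boot=50)
        rep = rep.set_index(["marker", "level"])
        assert not rep.loc["DLL3"]["evaluable"].any()
        assert bool(rep.loc[("TROP2", "intra_tumoral"), "evaluable"])
        # a single block cannot contribute cross-block pairs
        assert not bool(rep.loc[("TROP2", "intra_patient_inter_tumoral"), "evaluable"])

    def test_estimates_bounded_and_interval_contains_point(self):
        cohort, _, _ = generate_cohort(seed=11)
        rep = heterogeneity_report(
            cohort, ["TROP2", "DLL3"], seed=5, n_pairs=300, n_boot=200
        )
        ok = rep[rep["evaluable"]]
        assert ((ok["estimate"] >= 0) & (ok["estimate"] <= 1)).all()
        assert (ok["ci_low"] <= ok["estimate"]).all()
        assert (ok["estimate"] <= ok["ci_high"]).all()

    def test_identical_seed_gives_identical_report(self):
        cohort, _, _ = generate_cohort(seed=11)
        a = heterogeneity_report(cohort, ["TROP2"], seed=9, n_pairs=300, n_boot=100)
        b = heterogeneity_report(cohort, ["TROP2"], seed=9, n_pairs=300, n_boot=100)
        pd.testing.assert_frame_equal(a, b)

    def test_marker_specific_mixing_preserves_ordering(self):
        """Markers built with decreasing per-sample mixing keep their ordering
        in the estimated intra-tumoral heterogeneity."""
        mix = {"PSMA": 0.5, "CEACAM5": 0.3, "TROP2": 0.15, "DLL3": 0.05}
        models = {
            m: {"AR_pos_NE_neg": ZeroInflatedBeta(pi0=1 - p, a=8, b=2)}
            for m, p in mix.items()
        }
        cfg = SyntheticConfig(
            n_patients=40,
            sites_per_patient_mean=6.0,
            samples_per_site_mean=3.0,
            subtype_mixture={
                "AR_pos_NE_neg": 1.0, "AR_neg_NE_pos": 0.0,
                "AR_pos_NE_pos": 0.0, "AR_neg_NE_neg": 0.0,
            },
            markers=tuple(mix),
            marker_models=models,
        )
        cohort, _, _ = generate_cohort(cfg, seed=23)
        rep = heterogeneity_report(
            cohort, list(mix), levels=[GroupingLevel.intra_tumoral],
            seed=6, n_pairs=2000, n_boot=50,
        ).set_index("marker")
        est = rep["estimate"]
        assert est["PSMA"] > est["CEACAM5"] > est["TROP2"] > est["DLL3"]
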