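import itertools

import numpy as np
import pandas as pd
import pytest

from mctarget import (
    Cohort,
    CohortValidationError,
    GenomicsTable,
    binarize_expression,
    dichotomize_expression,
    fit_expression_genotype,
    fit_site_model,
    patient_positivity,
)
from conftest import cohort_from_scores


def _calls_and_genomics(cells, gene="RB1", status="ALT_BIALLELIC"):
    """Build one-observation-per-patient data from 2x2 cell counts
    (alt+pos, alt+neg, wt+pos, wt+neg)."""
    rows, grows = [], []
    k = 0
    for (alt, pos), n in zip(((1, 1), (1, 0), (0, 1), (0, 0)), cells):
        for _ in range(n):
            pid = f"P{k}"
            k += 1
            rows.append({"patient_id": pid, "positive": bool(pos)})
            grows.append(
                {"patient_id": pid, "gene": gene, "status": status if alt else "WT"}
            )
    return pd.DataFrame(rows), GenomicsTable(pd.DataFrame(grows))


class TestExpressionGenotype:
    def test_unclustered_fit_matches_cross_product_ratio(self):
        calls, genomics = _calls_and_genomics((20, 5, 5, 20))
        res = fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
        assert res.odds_ratio == pytest.approx(16.0, abs=1e-6)
        assert res.method == "logit"
        assert not res.flags

    def test_swapping_alt_and_wt_inverts_the_odds_ratio(self):
        calls, genomics = _calls_and_genomics((20, 5, 8, 16))
        res = fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
        calls_sw, genomics_sw = _calls_and_genomics((8, 16, 20, 5))
        res_sw = fit_expression_genotype(calls_sw, genomics_sw, "RB1", "biallelic_only")
        assert res_sw.odds_ratio == pytest.approx(1.0 / res.odds_ratio, rel=1e-6)

    def test_perfect_prediction_flags_complete_separation(self):
        calls, genomics = _calls_and_genomics((10, 0, 0, 10))
        res = fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
        assert "complete_separation" in res.flags
        assert not np.isfinite(res.odds_ratio)

    def test_single_empty_cell_is_boundary_with_exact_limits(self):
        calls, genomics = _calls_and_genomics((0, 5, 7, 8))
        res = fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
        assert {"quasi_separation", "boundary_estimate"} <= res.flags
        assert res.odds_ratio == 0.0
        assert res.ci_low == 0.0 and np.isfinite(res.ci_high)

    def test_separation_detected_on_all_small_tables(self):
        """Exhaustive enumeration of 2x2 tables with n <= 8: the flag is
        raised exactly when alteration status perfectly predicts outcome."""
        for cells in itertools.product(range(5), repeat=4):
            n11, n10, n01, n00 = cells
            if sum(cells) > 8:
                continue
            if n11 + n10 == 0 or n01 + n00 == 0:
                continue  # violates the >=1 altered and >=1 WT precondition
            calls, genomics = _calls_and_genomics(cells)
            res = fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
            perfectly_predicted = (n10 == 0 and n01 == 0) or (n11 == 0 and n00 == 0)
            assert ("complete_separation" in res.flags) == perfectly_predicted, cells

    def test_requires_both_alteration_classes(self):
        calls, genomics = _calls_and_genomics((5, 5, 0, 0))
        with pytest.raises(CohortValidationError, match="wild-type"):
            fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")

    def test_clustered_observations_use_gee(self):
        rng = np.random.default_rng(0)
        rows, grows = [], []
        for p in range(40):
            alt = p < 20
            base = 0.7 if alt else 0.3
            for s in range(3):
                rows.append({"patient_id": f"P{p}", "positive": bool(rng.random() < base)})
            grows.append(
                {"patient_id": f"P{p}", "gene": "AR", "status": "ALT_UNSPECIFIED" if alt else "WT"}
            )
        res = fit_expression_genotype(
            pd.DataFrame(rows), GenomicsTable(pd.DataFrame(grows)), "AR"
        )
        assert res.method == "gee_exchangeable"
        assert res.odds_ratio > 1

    def test_monoallelic_not_counted_under_biallelic_filter(self):
        calls, genomics = _calls_and_genomics((10, 5, 5, 10), status="ALT_MONOALLELIC")
        with pytest.raises(CohortValidationError):
            # no biallelic patient exists under this filter
            fit_expression_genotype(calls, genomics, "RB1", "biallelic_only")
        res = fit_expression_genotype(calls, genomics, "RB1", "any_alt")
        assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)


class TestDichotomize:
    def test_median_split_halves(self):
        assert dichotomize_expression([1, 2, 3, 4]).tolist() == [False, False, True, True]

    def test_ties_at_median_go_negative(self):
        assert dichotomize_expression([1, 2, 2, 4]).tolist() == [False, False, False, True]

    def test_constant_input_rejected(self):
        with pytest.raises(CohortValidationError, match="constant"):
            dichotomize_expression([3, 3, 3])

    def test_fixed_cutoff_matches_h_score_binarization(self):
        scores = [0.0, 19.9, 20.0, 55.0, 200.0]
        calls = dichotomize_expression(scores, rule="fixed_cutoff", cutoff=20)
        expected = [binarize_expression(h).positive for h in scores]
        assert calls.tolist() == expected


class TestSiteModel:
    def _flat_cohort(self, rng, effects, n_patients=15, sd=8.0):
        rows = []
        for p in range(n_patients):
            for s, e in effects.items():
                for k in range(2):
                    rows.append(
                        (
                            f"P{p}", s, f"{s}_T1", f"S{k}",
                            {"TROP2": float(np.clip(e + rng.normal(0, sd), 0, 200))},
                        )
                    )
        return cohort_from_scores(rows)

    def test_zero_patient_variance_reduces_to_ols(self):
        import statsmodels.formula.api as smf
        from mctarget import score_cohort

        rng = np.random.default_rng(4)
        cohort = self._flat_cohort(rng, {"vertebral_bone": 100.0, "liver": 80.0, "lung": 60.0})
        res = fit_site_model(cohort, "TROP2")
        df = score_cohort(cohort)
        ols = smf.ols(
            "h_score ~ C(site_label, Treatment('vertebral_bone'))",
            df[df.marker == "TROP2"],
        ).fit()
        assert res.var_patient == 0.0
        ref_mean = res.means.set_index("site").loc["vertebral_bone", "mean"]
        assert ref_mean == pytest.approx(ols.params.iloc[0], abs=1e-6)
        liver = res.differences.set_index("site").loc["liver", "difference"]
        assert liver == pytest.approx(
            ols.params["C(site_label, Treatment('vertebral_bone'))[T.liver]"], abs=1e-6
        )

    def test_single_site_gives_mean_only(self):
        rng = np.random.default_rng(4)
        cohort = self._flat_cohort(rng, {"liver": 80.0})
        res = fit_site_model(cohort, "TROP2")
        assert res.differences.empty
        assert res.means["mean"].iloc[0] == pytest.approx(80.0, abs=6.0)

    def test_singleton_site_flagged_wide_ci(self):
        rows = [
            ("P1", "liver", "liver_T1", "S1", {"TROP2": 50.0}),
            ("P1", "liver", "liver_T1", "S2", {"TROP2": 60.0}),
            ("P2", "liver", "liver_T1", "S1", {"TROP2": 40.0}),
            ("P2", "lung", "lung_T1", "S1", {"TROP2": 90.0}),
        ]
        res = fit_site_model(cohort_from_scores(rows), "TROP2", reference_site="liver")
        means = res.means.set_index("site")
        assert bool(means.loc["lung", "wide_ci"])
        assert not bool(means.loc["liver", "wide_ci"])

    def test_recovers_true_site_difference_with_nominal_coverage(self):
        """Liver 20 points below bone, patient SD 15, residual SD 20: the true
        difference lies inside its 95% CI in at least ~90% of replicates."""
        rng = np.random.default_rng(42)
        n_rep, covered = 120, 0
        for _ in range(n_rep):
            rows = []
            for p in range(50):
                u = rng.normal(0, 15)
                for s, e in (("vertebral_bone", 100.0), ("liver", 80.0)):
                    for k in range(2):
                        rows.append(
                            (
                                f"P{p}", s, f"{s}_T1", f"S{k}",
                                {"TROP2": float(np.clip(e + u + rng.normal(0, 20), 0, 200))},
                            )
                        )
            res = fit_site_model(cohort_from_scores(rows), "TROP2")
            d = res.differences.iloc[0]
            if d.ci_low <= -20.0 <= d.ci_high:
                covered += 1
        assert covered / n_rep >= 0.90


class TestPatientPositivity:
    def test_any_site_rule(self):
        cohort = cohort_from_scores(
            [
                ("P1", "liver", "B1", "S1", {"PSMA": 0.0}),
                ("P1", "lung", "B2", "S1", {"PSMA": 100.0}),
                ("P2", "liver", "B1", "S1", {"PSMA": 5.0}),
            ]
        )
        calls = patient_positivity(cohort, "PSMA").set_index("patient_id")["positive"]
        assert bool(calls["P1"]) is True and bool(calls["P2"]) is False
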