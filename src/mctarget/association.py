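"""Clustered expression models: anatomic-site means and expression-genotype odds.

Two model families:

* :func:`fit_site_model` — H-score on anatomic site, a linear mixed model
  with site fixed effects and a patient random intercept to absorb the
  repeated sampling of patients across sites.  Differences are reported
  against a reference site (vertebral bone by default).  When the patient
  variance component is estimated at the zero boundary the fit reduces
  exactly to ordinary least squares.

* :func:`fit_expression_genotype` — binarized expression on gene
  alteration status with patient-level clustering.  With one observation
  per patient this is ordinary logistic regression (the odds ratio equals
  the 2x2 cross-product ratio); with repeated observations a binomial GEE
  with exchangeable working correlation and robust standard errors is
  used.  Complete separation — the alteration status perfectly predicting
  the outcome — is detected up front and reported as a flag with no finite
  odds ratio; single empty cells (quasi-separation) are reported as
  boundary estimates with exact conditional confidence limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort_io import Cohort, CohortValidationError, GenomicsTable
from .scoring import DEFAULT_THRESHOLD, site_level_scores

__all__ = [
    "SiteMeansResult",
    "AssociationResult",
    "fit_site_model",
    "fit_expression_genotype",
    "dichotomize_expression",
    "patient_positivity",
    "association_report",
]

ALT_STATUSES_ANY = ("ALT_MONOALLELIC", "ALT_BIALLELIC", "ALT_UNSPECIFIED")


@dataclass
class SiteMeansResult:
    """Per-site mean H-scores and differences vs the reference site.

    ``means``: DataFrame (site, mean, ci_low, ci_high, n_samples, wide_ci).
    ``differences``: DataFrame (site, difference, ci_low, ci_high, p_value);
    the reference site's difference is identically zero and omitted.
    """

    marker: str
    reference_site: str
    means: pd.DataFrame
    differences: pd.DataFrame
    var_patient: float
    var_residual: float
    method: str  # "mixed" or "ols"


def fit_site_model(
    cohort: Cohort | pd.DataFrame,
    marker: str,
    reference_site: str = "vertebral_bone",
    threshold: float = DEFAULT_THRESHOLD,
) -> SiteMeansResult:
    """Linear mixed model of sample H-scores on anatomic site.

    Fixed effects for site, random intercept per patient, Wald 95% limits.
    Falls back to (or reduces exactly to) OLS when no patient contributes
    more than one sample or the patient variance is estimated at zero.
    Sites observed in a single sample are kept but flagged ``wide_ci``.
    """
    from .scoring import score_cohort

    df = score_cohort(cohort, threshold=threshold) if isinstance(cohort, Cohort) else cohort
    df = df[(df["marker"] == marker) & df["h_score"].notna()].copy()
    if df.empty:
        raise CohortValidationError(f"no scored samples for marker {marker!r}")
    sites = sorted(df["site_label"].unique())
    if reference_site not in sites:
        reference_site = sites[0]
    df["site_label"] = pd.Categorical(
        df["site_label"], categories=[reference_site] + [s for s in sites if s != reference_site]
    )

    single_obs_patients = df.groupby("patient_id").size().max() == 1
    formula = "h_score ~ C(site_label)"
    method = "mixed"
    if len(sites) == 1:
        method = "ols"
    if single_obs_patients:
        method = "ols"

    fit = None
    if method == "mixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["patient_id"])
            try:
                fit = model.fit(reml=True)
            except Exception as exc:
                raise RuntimeError(f"mixed model failed to converge for {marker}: {exc}") from exc
        var_patient = float(fit.cov_re.iloc[0, 0])
        var_residual = float(fit.scale)
        if var_patient <= 1e-4 * max(var_residual, 1.0):
            method = "ols"  # boundary: exact reduction to ordinary regression
    if method == "ols":
        fit = smf.ols(formula, df).fit()
        var_patient = 0.0
        var_residual = float(fit.scale)

    params = fit.params
    cov = fit.cov_params()
    # keep only fixed effects (mixedlm appends the variance parameter)
    fe_names = [n for n in params.index if n == "Intercept" or n.startswith("C(site_label)")]
    params = params[fe_names]
    cov = cov.loc[fe_names, fe_names]

    z = stats.norm.ppf(0.975)
    mean_rows, diff_rows = [], []
    n_per_site = df.groupby("site_label", observed=True).size()
    for site in [reference_site] + [s for s in sites if s != reference_site]:
        if site == reference_site:
            vec = pd.Series(0.0, index=params.index)
            vec["Intercept"] = 1.0
        else:
            vec = pd.Series(0.0, index=params.index)
            vec["Intercept"] = 1.0
            vec[f"C(site_label)[T.{site}]"] = 1.0
        mean = float(vec @ params)
        se = float(np.sqrt(vec @ cov @ vec))
        n_site = int(n_per_site.get(site, 0))
        mean_rows.append(
            {
                "site": site,
                "mean": mean,
                "ci_low": mean - z * se,
                "ci_high": mean + z * se,
                "n_samples": n_site,
                "wide_ci": n_site <= 1,
            }
        )
        if site != reference_site:
            cname = f"C(site_label)[T.{site}]"
            est = float(params[cname])
            dse = float(np.sqrt(cov.loc[cname, cname]))
            pval = float(2 * stats.norm.sf(abs(est) / dse)) if dse > 0 else np.nan
            diff_rows.append(
                {
                    "site": site,
                    "difference": est,
                    "ci_low": est - z * dse,
                    "ci_high": est + z * dse,
                    "p_value": pval,
                }
            )
    return SiteMeansResult(
        marker=marker,
        reference_site=reference_site,
        means=pd.DataFrame(mean_rows),
        differences=pd.DataFrame(diff_rows),
        var_patient=var_patient,
        var_residual=var_residual,
        method=method,
    )


@dataclass(frozen=True)
class AssociationResult:
    """Odds ratio of marker positivity given gene alteration, with flags.

    ``complete_separation`` means the alteration status perfectly predicted
    the outcome and no finite odds ratio exists; ``boundary_estimate`` marks
    a sample odds ratio of 0 or infinity (one empty cell) reported with
    exact conditional limits; ``quasi_separation`` accompanies it.
    """

    marker: str
    gene: str
    zygosity_filter: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flags: frozenset = frozenset()
    n_altered: int = 0
    n_wildtype: int = 0
    method: str = ""


def _alt_indicator(genomics: GenomicsTable, gene: str, zygosity_filter: str) -> pd.Series:
    sel = genomics.data[genomics.data["gene"] == gene]
    if sel.empty:
        raise CohortValidationError(f"gene {gene!r} not present in genomics table")
    if zygosity_filter == "any_alt":
        alt = sel["status"].isin(ALT_STATUSES_ANY)
    elif zygosity_filter == "biallelic_only":
        alt = sel["status"] == "ALT_BIALLELIC"
    else:
        raise ValueError(f"zygosity_filter must be 'any_alt' or 'biallelic_only', got {zygosity_filter!r}")
    return pd.Series(alt.values, index=sel["patient_id"].values)


def fit_expression_genotype(
    expression_calls: pd.DataFrame,
    genomics: GenomicsTable,
    gene: str,
    zygosity_filter: str = "any_alt",
    marker: str = "",
    alpha: float = 0.05,
) -> AssociationResult:
    """Logistic association of binary expression with gene alteration status.

    ``expression_calls`` needs columns ``patient_id`` and ``positive``
    (boolean); multiple rows per patient are treated as clustered repeated
    observations.  Requires at least one altered and one wild-type patient
    among those with expression calls.
    """
    calls = expression_calls.dropna(subset=["positive"]).copy()
    calls["positive"] = calls["positive"].astype(bool)
    alt = _alt_indicator(genomics, gene, zygosity_filter)
    calls = calls[calls["patient_id"].isin(alt.index)]
    if calls.empty:
        raise CohortValidationError("no overlap between expression calls and genomics")
    calls["alt"] = calls["patient_id"].map(alt).astype(bool)

    clusters = calls.groupby("patient_id")["alt"].first()
    n_alt_cluster = int(clusters.sum())
    n_wt_cluster = int((~clusters).sum())
    if n_alt_cluster == 0 or n_wt_cluster == 0:
        raise CohortValidationError(
            f"need at least one altered and one wild-type patient for {gene} "
            f"({n_alt_cluster} altered, {n_wt_cluster} wild-type)"
        )

    n11 = int((calls["alt"] & calls["positive"]).sum())    # alt, positive
    n10 = int((calls["alt"] & ~calls["positive"]).sum())   # alt, negative
    n01 = int((~calls["alt"] & calls["positive"]).sum())   # wt, positive
    n00 = int((~calls["alt"] & ~calls["positive"]).sum())  # wt, negative

    zero_cells = [c == 0 for c in (n11, n10, n01, n00)]
    complete = (n10 == 0 and n01 == 0) or (n11 == 0 and n00 == 0)
    if complete:
        return AssociationResult(
            marker=marker, gene=gene, zygosity_filter=zygosity_filter,
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
            flags=frozenset({"complete_separation"}),
            n_altered=n_alt_cluster, n_wildtype=n_wt_cluster, method="none",
        )
    if any(zero_cells):
        # sample OR at the boundary (0 or inf): exact conditional limits
        table = np.array([[n11, n10], [n01, n00]])
        res = stats.contingency.odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        point = 0.0 if (n11 == 0 or n00 == 0) else np.inf
        p = float(stats.fisher_exact(table)[1])
        return AssociationResult(
            marker=marker, gene=gene, zygosity_filter=zygosity_filter,
            odds_ratio=point, ci_low=float(ci.low), ci_high=float(ci.high),
            p_value=p,
            flags=frozenset({"quasi_separation", "boundary_estimate"}),
            n_altered=n_alt_cluster, n_wildtype=n_wt_cluster, method="exact_conditional",
        )

    y = calls["positive"].astype(float).values
    X = sm.add_constant(calls["alt"].astype(float).values)
    one_obs_per_patient = calls.groupby("patient_id").size().max() == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if one_obs_per_patient:
            fit = sm.Logit(y, X).fit(disp=False)
            method = "logit"
        else:
            fit = sm.GEE(
                y, X, groups=calls["patient_id"].values,
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
            method = "gee_exchangeable"
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(1 - alpha / 2)
    return AssociationResult(
        marker=marker, gene=gene, zygosity_filter=zygosity_filter,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(2 * stats.norm.sf(abs(beta) / se)),
        flags=frozenset(),
        n_altered=n_alt_cluster, n_wildtype=n_wt_cluster, method=method,
    )


def dichotomize_expression(
    values: Sequence[float] | pd.Series,
    rule: str = "median_split",
    cutoff: float | None = None,
    q: float | None = None,
) -> np.ndarray:
    """Binary expression calls from continuous values (FPKM-like or H-score).

    Rules: ``median_split`` (default) and ``quantile`` call positive above
    the cut, with ties at the cut going to the negative class;
    ``fixed_cutoff`` is inclusive (value >= cutoff is positive), matching
    the H-score positivity convention.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise CohortValidationError("dichotomization requires at least 2 subjects")
    if rule == "median_split":
        cut = np.median(vals)
        if np.all(vals == vals[0]):
            raise CohortValidationError("constant input: no median split exists")
        return vals > cut
    if rule == "quantile":
        if q is None or not (0 < q < 1):
            raise ValueError("quantile rule requires 0 < q < 1")
        cut = np.quantile(vals, q)
        if np.all(vals == vals[0]):
            raise CohortValidationError("constant input: no quantile split exists")
        return vals > cut
    if rule == "fixed_cutoff":
        if cutoff is None:
            raise ValueError("fixed_cutoff rule requires a cutoff")
        return vals >= cutoff
    raise ValueError(f"unknown rule {rule!r}")


def patient_positivity(
    cohort: Cohort | pd.DataFrame,
    marker: str,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "any_site",
) -> pd.DataFrame:
    """Per-patient binary positivity for a marker.

    ``any_site`` (default): positive when any lesion (site-level aggregate)
    reaches the cut — appropriate when genomics is per patient.
    ``per_sample``: one row per lesion, for clustered analyses.
    """
    table = site_level_scores(cohort, threshold=threshold)
    if marker not in table.columns:
        raise CohortValidationError(f"marker {marker!r} not scored in this cohort")
    table = table.dropna(subset=[marker])
    table["positive"] = table[marker] >= threshold
    if mode == "any_site":
        out = table.groupby("patient_id", as_index=False)["positive"].any()
        return out
    if mode == "per_sample":
        return table[["patient_id", "positive"]].reset_index(drop=True)
    raise ValueError(f"mode must be 'any_site' or 'per_sample', got {mode!r}")


def association_report(
    cohort: Cohort | pd.DataFrame,
    genomics: GenomicsTable,
    markers: Sequence[str],
    genes: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "any_site",
    rb1_both_zygosities: bool = True,
) -> pd.DataFrame:
    """Odds-ratio table over (marker, gene) combinations.

    RB1 is analyzed twice by default: restricted to biallelic inactivation
    and combining monoallelic with biallelic alterations.  Rows for which
    the model is not estimable (all patients altered, or wild-type) are
    flagged ``not_estimable``.
    """
    rows = []
    for m in markers:
        calls = patient_positivity(cohort, m, threshold=threshold, mode=mode)
        for g in genes:
            filters = ["any_alt"]
            if rb1_both_zygosities and g == "RB1":
                filters = ["biallelic_only", "any_alt"]
            for zf in filters:
                try:
                    res = fit_expression_genotype(calls, genomics, g, zygosity_filter=zf, marker=m)
                except CohortValidationError as exc:
                    rows.append(
                        {
                            "marker": m, "gene": g, "zygosity_filter": zf,
                            "odds_ratio": np.nan, "ci_low": np.nan,
                            "ci_high": np.nan, "p_value": np.nan,
                            "flags": "not_estimable", "note": str(exc),
                        }
                    )
                    continue
                rows.append(
                    {
                        "marker": m, "gene": g, "zygosity_filter": zf,
                        "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "p_value": res.p_value,
                        "flags": ";".join(sorted(res.flags)), "note": res.method,
                    }
                )
    return pd.DataFrame(rows)
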