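"""Synthetic multi-site cohort generator with analytically known ground truth.

Emulates the hierarchical structure of a rapid-autopsy CRPC cohort: ~52
patients, ~7 metastatic sites each (~372 sites), ~2 samples per site
(~753 samples).  Each patient carries a dominant molecular subtype drawn
from a four-class mixture; each site shares it with probability
``dominant_subtype_fidelity`` (else another subtype, creating the
mixed-phenotype patients that drive inter-tumoral heterogeneity).  Marker
H-scores are drawn per (marker, site subtype) from a zero-inflated scaled
Beta on [0, 200] — a point mass at zero for non-expressing tumors plus a
Beta-distributed expressing component — and are emitted as staining-level
profiles so the scoring path is exercised end to end.  Gene alteration
statuses are drawn per patient conditional on the dominant subtype.

Every downstream estimand has a closed form under this model:
:func:`true_discordance` gives the exact within-unit pair-discordance
probability per level, and :func:`true_log_odds_ratio` the exact
patient-level log odds ratio between alteration and any-site positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (
    DEFAULT_MARKERS,
    DEFAULT_SITES,
    Cohort,
    GenomicsTable,
)
from .heterogeneity import GroupingLevel
from .scoring import DEFAULT_THRESHOLD, MolecularSubtype

__all__ = [
    "ConfigError",
    "ZeroInflatedBeta",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "true_discordance",
    "true_log_odds_ratio",
    "make_published_fixtures",
]

SUBTYPES = tuple(s.value for s in MolecularSubtype)


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class ZeroInflatedBeta:
    """H-score distribution: mass ``pi0`` at zero, else 200 * Beta(a, b)."""

    pi0: float
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ConfigError(f"pi0 = {self.pi0!r} outside [0, 1]")
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("Beta shape parameters must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        zeros = rng.random(size) < self.pi0
        vals = 200.0 * rng.beta(self.a, self.b, size=size)
        vals[zeros] = 0.0
        return vals

    def positivity_prob(self, threshold: float = DEFAULT_THRESHOLD) -> float:
        """Exact P(H >= threshold)."""
        return (1.0 - self.pi0) * float(stats.beta.sf(threshold / 200.0, self.a, self.b))

    def mean(self) -> float:
        return (1.0 - self.pi0) * 200.0 * self.a / (self.a + self.b)


def _zib(pi0, a, b):
    return ZeroInflatedBeta(pi0, a, b)


#: Per (marker, subtype) H-score models, tuned to the qualitative pattern of
#: subtype-conditional expression: TROP2 high outside NEPC, DLL3/CEACAM5
#: concentrated in NEPC, PSMA high in AR-driven disease, axis markers tracking
#: their own subtype axis.
DEFAULT_MARKER_MODELS: dict[str, dict[str, ZeroInflatedBeta]] = {
    "TROP2": {
        "AR_pos_NE_neg": _zib(0.04, 5.0, 0.55),
        "AR_neg_NE_pos": _zib(0.60, 1.0, 2.0),
        "AR_pos_NE_pos": _zib(0.05, 4.0, 0.70),
        "AR_neg_NE_neg": _zib(0.04, 5.0, 0.55),
    },
    "DLL3": {
        "AR_pos_NE_neg": _zib(0.92, 1.0, 6.0),
        "AR_neg_NE_pos": _zib(0.18, 1.6, 1.8),
        "AR_pos_NE_pos": _zib(0.50, 1.0, 3.0),
        "AR_neg_NE_neg": _zib(0.80, 1.0, 4.0),
    },
    "CEACAM5": {
        "AR_pos_NE_neg": _zib(0.75, 1.0, 4.0),
        "AR_neg_NE_pos": _zib(0.30, 1.0, 1.8),
        "AR_pos_NE_pos": _zib(0.55, 1.0, 2.5),
        "AR_neg_NE_neg": _zib(0.50, 1.0, 2.5),
    },
    "PSMA": {
        "AR_pos_NE_neg": _zib(0.10, 1.8, 1.1),
        "AR_neg_NE_pos": _zib(0.80, 1.0, 5.0),
        "AR_pos_NE_pos": _zib(0.20, 2.0, 1.0),
        "AR_neg_NE_neg": _zib(0.45, 1.0, 2.2),
    },
    "AR": {
        "AR_pos_NE_neg": _zib(0.02, 6.0, 0.8),
        "AR_pos_NE_pos": _zib(0.02, 6.0, 0.8),
        "AR_neg_NE_pos": _zib(0.88, 1.0, 8.0),
        "AR_neg_NE_neg": _zib(0.88, 1.0, 8.0),
    },
    "NKX3.1": {
        "AR_pos_NE_neg": _zib(0.03, 5.0, 0.9),
        "AR_pos_NE_pos": _zib(0.03, 5.0, 0.9),
        "AR_neg_NE_pos": _zib(0.85, 1.0, 8.0),
        "AR_neg_NE_neg": _zib(0.85, 1.0, 8.0),
    },
    "SYP": {
        "AR_neg_NE_pos": _zib(0.02, 4.0, 0.8),
        "AR_pos_NE_pos": _zib(0.02, 4.0, 0.8),
        "AR_pos_NE_neg": _zib(0.88, 1.0, 8.0),
        "AR_neg_NE_neg": _zib(0.88, 1.0, 8.0),
    },
    "INSM1": {
        "AR_neg_NE_pos": _zib(0.05, 3.5, 0.9),
        "AR_pos_NE_pos": _zib(0.05, 3.5, 0.9),
        "AR_pos_NE_neg": _zib(0.90, 1.0, 8.0),
        "AR_neg_NE_neg": _zib(0.90, 1.0, 8.0),
    },
}

#: Per-gene status probabilities (WT, monoallelic, biallelic) conditional on
#: dominant subtype; "default" applies to subtypes not listed.  RB1 biallelic
#: loss is enriched in NEPC and AR alterations in AR-driven disease.
DEFAULT_ALTERATION_MODEL: dict[str, dict[str, tuple[float, float, float]]] = {
    "AR": {
        "AR_pos_NE_neg": (0.40, 0.10, 0.50),
        "AR_pos_NE_pos": (0.50, 0.10, 0.40),
        "default": (0.78, 0.10, 0.12),
    },
    "RB1": {"AR_neg_NE_pos": (0.20, 0.10, 0.70), "default": (0.70, 0.15, 0.15)},
    "TP53": {"default": (0.35, 0.15, 0.50)},
    "PTEN": {"default": (0.50, 0.15, 0.35)},
    "BRCA2": {"default": (0.85, 0.05, 0.10)},
    "CHD1": {"default": (0.88, 0.05, 0.07)},
    "SPOP": {"default": (0.90, 0.05, 0.05)},
}

#: Anatomic-site label frequencies (bone-heavy, frequent liver/soft tissue).
DEFAULT_SITE_WEIGHTS: dict[str, float] = {
    "vertebral_bone": 0.20,
    "nonvertebral_bone": 0.18,
    "liver": 0.15,
    "lymph_node": 0.15,
    "lung": 0.08,
    "soft_tissue": 0.08,
    "prostate": 0.06,
    "adrenal": 0.04,
    "brain": 0.02,
    "peritoneum": 0.02,
    "other": 0.02,
}

DEFAULT_SUBTYPE_MIXTURE: dict[str, float] = {
    "AR_pos_NE_neg": 0.62,
    "AR_neg_NE_pos": 0.19,
    "AR_pos_NE_pos": 0.07,
    "AR_neg_NE_neg": 0.12,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults target the emulated cohort scale
    (52 patients, ~372 sites, ~753 samples, published subtype composition).

    ``sites_per_patient_mean`` parameterizes a zero-truncated Poisson capped
    at the number of site labels; ``samples_per_site_mean`` the shifted
    Poisson 1 + Pois(mean - 1).  ``dominant_subtype_fidelity`` is the
    probability that a site shares its patient's dominant subtype.
    """

    n_patients: int = 52
    sites_per_patient_mean: float = 7.0
    samples_per_site_mean: float = 2.0
    subtype_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MIXTURE)
    )
    dominant_subtype_fidelity: float = 0.9
    markers: tuple[str, ...] = DEFAULT_MARKERS
    marker_models: Mapping[str, Mapping[str, ZeroInflatedBeta]] = field(
        default_factory=lambda: DEFAULT_MARKER_MODELS
    )
    alteration_model: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: DEFAULT_ALTERATION_MODEL
    )
    site_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_WEIGHTS))
    site_vocabulary: tuple[str, ...] = DEFAULT_SITES
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        probs = np.array([self.subtype_mixture.get(s, 0.0) for s in SUBTYPES])
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-6:
            raise ConfigError(f"subtype mixture must be probabilities summing to 1, got {dict(self.subtype_mixture)}")
        if not (0.0 <= self.dominant_subtype_fidelity <= 1.0):
            raise ConfigError("dominant_subtype_fidelity must be in [0, 1]")
        for m in self.markers:
            if m not in self.marker_models:
                raise ConfigError(f"no marker model for {m!r}")
        for g, per_subtype in self.alteration_model.items():
            for key, p in per_subtype.items():
                arr = np.array(p, dtype=float)
                if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-6:
                    raise ConfigError(f"alteration probabilities for {g}/{key} must sum to 1")

    # -- distribution helpers -------------------------------------------------

    def _mixture(self) -> np.ndarray:
        return np.array([self.subtype_mixture.get(s, 0.0) for s in SUBTYPES])

    def model_for(self, marker: str, subtype: str) -> ZeroInflatedBeta:
        try:
            return self.marker_models[marker][subtype]
        except KeyError:
            raise ConfigError(f"no model for marker {marker!r} in subtype {subtype!r}") from None

    def alteration_probs(self, gene: str, subtype: str) -> tuple[float, float, float]:
        per = self.alteration_model[gene]
        return per.get(subtype, per.get("default", (1.0, 0.0, 0.0)))

    def site_subtype_marginal(self) -> dict[str, float]:
        """P(site subtype = s) under dominant-subtype mixing."""
        pi = self._mixture()
        out = {s: 0.0 for s in SUBTYPES}
        for j, d in enumerate(SUBTYPES):
            if pi[j] == 0:
                continue
            cond = self.site_subtype_given_dominant(d)
            for s in SUBTYPES:
                out[s] += pi[j] * cond[s]
        return out

    def site_subtype_given_dominant(self, dominant: str) -> dict[str, float]:
        pi = self._mixture()
        f = self.dominant_subtype_fidelity
        d = SUBTYPES.index(dominant)
        if pi[d] >= 1.0 - 1e-12:
            return {s: 1.0 if s == dominant else 0.0 for s in SUBTYPES}
        out = {}
        for i, s in enumerate(SUBTYPES):
            out[s] = f if i == d else (1.0 - f) * pi[i] / (1.0 - pi[d])
        return out

    def _sites_per_patient_pmf(self) -> np.ndarray:
        """Zero-truncated Poisson capped at the vocabulary size; pmf over 1..cap."""
        cap = len(self.site_vocabulary)
        lam = self.sites_per_patient_mean
        pmf = stats.poisson.pmf(np.arange(1, cap + 1), lam)
        pmf[-1] += stats.poisson.sf(cap, lam)
        pmf /= 1.0 - stats.poisson.pmf(0, lam)
        return pmf / pmf.sum()


@dataclass
class GroundTruth:
    """Exact estimands implied by a (config, seed) draw.

    ``discordance`` maps (marker, level value) to the exact within-unit
    pair-discordance probability; ``log_odds_ratios`` maps (marker, gene,
    zygosity filter) to the exact patient-level log OR of any-site
    positivity on alteration status.
    """

    patient_subtypes: dict[str, str]
    site_subtypes: dict[tuple[str, str], str]
    discordance: dict[tuple[str, str], float]
    log_odds_ratios: dict[tuple[str, str, str], float]
    config: SyntheticConfig
    seed: int


# ---------------------------------------------------------------------------
# analytic ground truth


def true_discordance(config: SyntheticConfig, marker: str | None = None) -> dict:
    """Exact per-(marker, level) discordance probabilities under the config.

    Intra-tumoral: samples within a block are iid given the site subtype, so
    the expected within-unit discordant-pair fraction is
    ``sum_s P(S=s) * 2 p_s (1 - p_s)``.  Inter-tumoral: cross-block pairs
    have independent site subtypes given the dominant subtype, giving
    ``sum_d pi_d * 2 q_d (1 - q_d)`` with ``q_d`` the site-marginal
    positivity given dominance.  Both are exact expectations of the
    unit-then-pair sampler (unit eligibility is independent of the calls).
    """
    markers = [marker] if marker else list(config.markers)
    pi = config._mixture()
    marginal = config.site_subtype_marginal()
    out = {}
    for m in markers:
        p_s = {
            s: (
                config.model_for(m, s).positivity_prob(config.threshold)
                if marginal[s] > 0
                else 0.0
            )
            for s in SUBTYPES
        }
        intra = sum(marginal[s] * 2.0 * p_s[s] * (1.0 - p_s[s]) for s in SUBTYPES)
        inter = 0.0
        for j, d in enumerate(SUBTYPES):
            if pi[j] == 0:
                continue
            cond = config.site_subtype_given_dominant(d)
            q_d = sum(cond[s] * p_s[s] for s in SUBTYPES)
            inter += pi[j] * 2.0 * q_d * (1.0 - q_d)
        out[(m, GroupingLevel.intra_tumoral.value)] = intra
        out[(m, GroupingLevel.intra_patient_inter_tumoral.value)] = inter
    return out


def _site_positive_prob(config: SyntheticConfig, p_sample: float) -> float:
    """P(any sample in a site is positive), sites holding 1 + Pois(mean-1) samples."""
    mu = config.samples_per_site_mean - 1.0
    return 1.0 - (1.0 - p_sample) * float(np.exp(-mu * p_sample))


def _patient_positive_prob(config: SyntheticConfig, dominant: str, marker: str) -> float:
    """P(any site positive | dominant subtype), exact over the site-count pmf."""
    cond = config.site_subtype_given_dominant(dominant)
    p_s = {
        s: (
            config.model_for(marker, s).positivity_prob(config.threshold)
            if cond[s] > 0
            else 0.0
        )
        for s in SUBTYPES
    }
    q = sum(cond[s] * _site_positive_prob(config, p_s[s]) for s in SUBTYPES)
    pmf = config._sites_per_patient_pmf()
    ks = np.arange(1, len(pmf) + 1)
    return 1.0 - float(np.sum(pmf * (1.0 - q) ** ks))


def true_log_odds_ratio(
    config: SyntheticConfig, marker: str, gene: str, zygosity_filter: str = "any_alt"
) -> float:
    """Exact patient-level log OR of any-site positivity on alteration status."""
    pi = config._mixture()
    p11 = p10 = p01 = p00 = 0.0
    for j, d in enumerate(SUBTYPES):
        if pi[j] == 0:
            continue
        wt, mono, bi = config.alteration_probs(gene, d)
        p_alt = bi if zygosity_filter == "biallelic_only" else mono + bi
        p_pos = _patient_positive_prob(config, d, marker)
        p11 += pi[j] * p_alt * p_pos
        p10 += pi[j] * p_alt * (1.0 - p_pos)
        p01 += pi[j] * (1.0 - p_alt) * p_pos
        p00 += pi[j] * (1.0 - p_alt) * (1.0 - p_pos)
    if min(p11, p10, p01, p00) <= 0.0:
        return np.inf if p10 * p01 == 0 else -np.inf
    return float(np.log(p11 * p00 / (p10 * p01)))


# ---------------------------------------------------------------------------
# generation


def _profile_from_h(h: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Random valid staining profile whose H-score is exactly ``h``.

    With pct2 drawn in [max(0, h-100), h/2], setting pct1 = h - 2*pct2 and
    pct0 = 100 - h + pct2 yields nonnegative fractions summing to 100.
    """
    lo, hi = max(0.0, h - 100.0), h / 2.0
    p2 = rng.uniform(lo, hi) if hi > lo else lo
    p1 = h - 2.0 * p2
    p0 = 100.0 - h + p2
    return p0, p1, p2


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Cohort, GenomicsTable, GroundTruth]:
    """Draw a full synthetic cohort, genomics table and its ground truth.

    Fully reproducible: identical (config, seed) give identical outputs.
    H-scores are emitted only as staining-level profiles, so downstream
    scoring must run :func:`mctarget.scoring.compute_h_score`.
    """
    if seed is None:
        raise ConfigError("seed is required")
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    mixture = config._mixture()
    site_labels = list(config.site_weights)
    site_w = np.array([config.site_weights[s] for s in site_labels], dtype=float)
    site_w /= site_w.sum()
    sites_pmf = config._sites_per_patient_pmf()

    rows = []
    patient_subtypes: dict[str, str] = {}
    site_subtypes: dict[tuple[str, str], str] = {}
    genomics_rows = []
    pad = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{pad}d}"
        dominant = SUBTYPES[rng.choice(len(SUBTYPES), p=mixture)]
        patient_subtypes[pid] = dominant
        cond = config.site_subtype_given_dominant(dominant)
        cond_p = np.array([cond[s] for s in SUBTYPES])

        n_sites = 1 + rng.choice(len(sites_pmf), p=sites_pmf)
        labels = rng.choice(len(site_labels), size=min(n_sites, len(site_labels)),
                            replace=False, p=site_w)
        for li in labels:
            site = site_labels[li]
            s_subtype = SUBTYPES[rng.choice(len(SUBTYPES), p=cond_p)]
            site_subtypes[(pid, site)] = s_subtype
            block = f"{site}_T1"
            n_samples = 1 + rng.poisson(max(config.samples_per_site_mean - 1.0, 0.0))
            for k in range(n_samples):
                sid = f"S{k + 1}"
                for m in config.markers:
                    h = float(config.model_for(m, s_subtype).sample(rng, 1)[0])
                    p0, p1, p2 = _profile_from_h(h, rng)
                    rows.append(
                        {
                            "patient_id": pid, "site_label": site,
                            "block_id": block, "sample_id": sid, "marker": m,
                            "h_score": np.nan,
                            "pct_level0": p0, "pct_level1": p1, "pct_level2": p2,
                        }
                    )
        for gene in config.alteration_model:
            wt, mono, bi = config.alteration_probs(gene, dominant)
            status = ("WT", "ALT_MONOALLELIC", "ALT_BIALLELIC")[
                rng.choice(3, p=np.array([wt, mono, bi]) / (wt + mono + bi))
            ]
            genomics_rows.append({"patient_id": pid, "gene": gene, "status": status})

    cohort = Cohort(
        pd.DataFrame(rows),
        markers=tuple(config.markers),
        site_vocabulary=config.site_vocabulary,
        provenance=f"synthetic cohort, seed={seed}",
    )
    genomics = GenomicsTable(
        pd.DataFrame(genomics_rows), genes=tuple(config.alteration_model)
    )
    log_ors = {}
    for m in config.markers:
        for gene in config.alteration_model:
            log_ors[(m, gene, "any_alt")] = true_log_odds_ratio(config, m, gene, "any_alt")
            if gene == "RB1":
                log_ors[(m, gene, "biallelic_only")] = true_log_odds_ratio(
                    config, m, gene, "biallelic_only"
                )
    truth = GroundTruth(
        patient_subtypes=patient_subtypes,
        site_subtypes=site_subtypes,
        discordance=true_discordance(config),
        log_odds_ratios=log_ors,
        config=config,
        seed=seed,
    )
    return cohort, genomics, truth


# ---------------------------------------------------------------------------
# fixed fixtures reproducing published summary counts (synthetic stand-ins:
# the underlying per-sample tables are not published, so these encode only
# the reported site-level contingency and per-patient category patterns)


def _fixture_rows(pid, site, markers_h, block=None, sample="S1"):
    block = block or f"{site}_T1"
    return [
        {
            "patient_id": pid, "site_label": site, "block_id": block,
            "sample_id": sample, "marker": m, "h_score": h,
            "pct_level0": np.nan, "pct_level1": np.nan, "pct_level2": np.nan,
        }
        for m, h in markers_h.items()
    ]


def _contingency_fixture(
    counts: tuple[int, int, int, int],
    marker_a: str,
    marker_b: str,
    axis_scores: Mapping[str, float],
    n_patients: int = 52,
) -> Cohort:
    """Site-level lesions with the given (dual, a_only, b_only, neither) counts."""
    labels = [s for s in DEFAULT_SITES]
    rows = []
    pattern = (
        [(100.0, 100.0)] * counts[0]
        + [(100.0, 0.0)] * counts[1]
        + [(0.0, 100.0)] * counts[2]
        + [(0.0, 0.0)] * counts[3]
    )
    per_patient: dict[str, int] = {}
    for idx, (ha, hb) in enumerate(pattern):
        pid = f"F{idx % n_patients + 1:02d}"
        k = per_patient.get(pid, 0)
        per_patient[pid] = k + 1
        site = labels[k % len(labels)]
        block = f"{site}_T{k // len(labels) + 1}"
        scores = dict(axis_scores)
        scores[marker_a] = ha
        scores[marker_b] = hb
        rows.extend(_fixture_rows(pid, site, scores, block=block))
    return Cohort(pd.DataFrame(rows))


def _expressor_fixture(
    marker: str, n_negative: int, n_heterogeneous: int, n_positive: int,
    n_unscored: int = 0,
) -> Cohort:
    rows = []
    patterns = (
        [(0.0, 5.0)] * n_negative
        + [(0.0, 120.0)] * n_heterogeneous
        + [(150.0, 200.0)] * n_positive
        + [(np.nan, np.nan)] * n_unscored
    )
    for idx, (h1, h2) in enumerate(patterns):
        pid = f"E{idx + 1:02d}"
        rows.extend(_fixture_rows(pid, "liver", {marker: h1}))
        rows.extend(_fixture_rows(pid, "lung", {marker: h2}))
    return Cohort(pd.DataFrame(rows))


def make_published_fixtures() -> dict[str, Cohort]:
    """Deterministic fixtures encoding published site-level summary counts.

    * ``ar_pos_trop2_psma`` — 304 AR+/NE- lesions with PSMA/TROP2 positivity
      counts (dual, PSMA only, TROP2 only, neither) = (233, 7, 61, 3).
    * ``nepc_dll3_ceacam5`` — 71 AR-/NE+ lesions with DLL3/CEACAM5 counts
      (38, 21, 3, 9).
    * ``dll3_expressors`` / ``trop2_expressors`` / ``ceacam5_expressors`` —
      per-patient category patterns (39, 9, 4), (6, 12, 34) and (26, 22, 3,
      with one unscored patient giving 51 evaluable).
    """
    ar_pos_axis = {"AR": 200.0, "NKX3.1": 180.0, "SYP": 0.0, "INSM1": 0.0}
    nepc_axis = {"AR": 0.0, "NKX3.1": 0.0, "SYP": 150.0, "INSM1": 100.0}
    return {
        "ar_pos_trop2_psma": _contingency_fixture((233, 7, 61, 3), "PSMA", "TROP2", ar_pos_axis),
        "nepc_dll3_ceacam5": _contingency_fixture((38, 21, 3, 9), "DLL3", "CEACAM5", nepc_axis),
        "dll3_expressors": _expressor_fixture("DLL3", 39, 9, 4),
        "trop2_expressors": _expressor_fixture("TROP2", 6, 12, 34),
        "ceacam5_expressors": _expressor_fixture("CEACAM5", 26, 22, 3, n_unscored=1),
    }
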