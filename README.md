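# mctarget

Cohort-level analysis of cell-surface therapeutic-target expression
(TROP2, DLL3, CEACAM5, PSMA) in multi-site metastatic
castration-resistant prostate cancer (mCRPC).

Rapid-autopsy cohorts sample many metastatic sites per patient, which
makes it possible to ask not only *whether* a tumor expresses a drug
target but *how consistently* it does so across a patient's disease —
the question that decides whether an antibody-drug conjugate or
radioligand will find its antigen in every lesion. `mctarget` implements
the full statistical toolchain for such cohorts:

* **H-score scoring** — semiquantitative IHC on the two-level intensity
  convention, `H = 0·p₀ + 1·p₁ + 2·p₂` for percentages `pₖ` of cells at
  staining intensity `k`, range 0–200; positivity at the inclusive cut
  `H ≥ 20`.
* **Molecular subtyping** — the four-way AR/NE cross from
  androgen-receptor–axis markers (AR, NKX3.1) and neuroendocrine markers
  (SYP, INSM1): AR+/NE− adenocarcinoma, AR−/NE+ (NEPC), AR+/NE+
  amphicrine, AR−/NE− double-negative.
* **Co-expression and expressor categories** — pairwise 2×2 positivity
  contingencies over lesions per subtype, and per-patient classification
  as uniformly negative / heterogeneous / uniformly positive across
  sites.
* **Heterogeneity index** — the probability that a random pair of
  binarized calls from the same grouping unit is discordant
  (exactly one member `≥ 20`), at two levels: within one tumor block
  (intra-tumoral) and within one patient across blocks (inter-tumoral).
  Point estimates by random sampling of 1000 pairs; exact enumeration as
  oracle (for a unit with `p` positives and `n` negatives the discordant
  fraction is `p·n / C(p+n, 2)`); 95% limits by bias-corrected and
  accelerated (BCa) bootstrap resampling the grouping units.
* **Clustered association models** — linear mixed models of H-score on
  anatomic site with patient random intercepts, and logistic models of
  positivity on gene alteration status (AR, RB1, TP53, PTEN, BRCA2,
  CHD1, SPOP; monoallelic vs biallelic) with patient clustering and
  explicit complete-separation detection.
* **Synthetic cohorts** — a hierarchical generator
  (patient → dominant subtype → site subtype → staining profiles) with
  closed-form ground truth for every estimand, used throughout the test
  suite.

## Worked example

```python
from mctarget import (
    generate_cohort, heterogeneity_report, coexpression_counts,
    summarize_percentages, make_published_fixtures,
)

# published PSMA/TROP2 lesion counts in AR+/NE- disease
fixtures = make_published_fixtures()
s = coexpression_counts(fixtures["ar_pos_trop2_psma"], "PSMA", "TROP2",
                        subtype_filter="AR_pos_NE_neg")
print("counts:", s.counts(), "n =", s.n_total)
print("percentages:", summarize_percentages(s))

# a synthetic 52-patient cohort and its heterogeneity indices
cohort, genomics, truth = generate_cohort(seed=17)
rep = heterogeneity_report(cohort, ["TROP2", "DLL3"],
                           n_pairs=1000, n_boot=1000, seed=17)
print(rep[["marker", "level", "estimate", "ci_low", "ci_high", "n_units"]]
      .round(3).to_string(index=False))
```

prints

```
counts: (233, 7, 61, 3) n = 304
percentages: (77.0, 2.0, 20.0, 1.0)
marker                       level  estimate  ci_low  ci_high  n_units
 TROP2               intra_tumoral     0.130   0.091    0.175      226
 TROP2 intra_patient_inter_tumoral     0.190   0.131    0.274       52
  DLL3               intra_tumoral     0.132   0.082    0.155      226
  DLL3 intra_patient_inter_tumoral     0.171   0.116    0.223       52
```

Reading: 77% of the 304 AR+/NE− lesions co-express PSMA and TROP2 and
only 1% express neither — dual-target coverage is nearly complete in
adenocarcinoma.  In the synthetic cohort, a random pair of TROP2 calls
from two different tumors of the same patient disagrees 19% of the time
(95% BCa CI 13–27%), versus 13% for two samples of the same tumor —
between-tumor heterogeneity exceeds within-tumor heterogeneity, as the
hierarchical model that generated the cohort dictates (analytic truths
0.193 and 0.153).

The same stages are available from the shell:

```bash
mctarget run --simulate default --seed 17 --out run1/
mctarget heterogeneity --cohort run1/cohort.csv --markers TROP2,PSMA \
    --n-pairs 1000 --n-boot 1000 --seed 17 --out het.csv
```

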