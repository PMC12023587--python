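# Methods

## The classification problem

Endometrial carcinomas fall into four prognostic molecular groups —
POLE (ultramutated), MSI-H (hypermutated, microsatellite-unstable),
copy-number high (CNH, TP53-mutant/serous-like) and copy-number low
(CNL, TP53-wild-type/endometrioid) — originally defined by multi-platform
genomics and later surrogated by combined IHC + sequencing classifiers
(ProMisE and related schemes). `ecsubtype` implements a single-assay
version of this classification: all evidence (small variants,
microsatellite read-length histograms, copy-number segments) comes from
one targeted NGS panel, and samples are assigned by a strict hierarchy:

1. **POLE** if a pathogenic *POLE* variant is present (hotspot list, or
   any nonsynonymous exonuclease-domain variant in an ultramutated
   sample);
2. otherwise **MSI-H** if the sample is microsatellite-unstable *and*
   hypermutated;
3. otherwise (MSI-L and MSS are treated identically) **CNH** or **CNL**
   by the copy-number rule.

The hierarchy is total: every sample with evaluable markers receives
exactly one label; missing layers yield an explicit `unclassifiable`
value rather than an exception or a silent drop.

## Marker definitions and tunable thresholds

All thresholds live in `CallerConfig` (JSON-serializable, overridable
per CLI flag). Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `vaf_min` | 0.05 | panel sensitivity filter; per-gene overrides support the higher hotspot sensitivity (0.01) of wide panels |
| `tmb_ultra_threshold` | 100 mut/Mb | ultramutation; conventional cutoff, the concept is named but not quantified by the classification scheme |
| `tmb_hyper_threshold` | 10 mut/Mb | hypermutation required alongside MSI for the MSI-H call; set to 0 to make the MSI call purely locus-based |
| `baseline_support_floor` | 0.01 | a repeat length is "novel" if its baseline probability is below this |
| `msi_novel_length_tau` | 0.10 | per-locus instability: novel-read fraction must strictly exceed this |
| `msi_h_locus_fraction` / `msi_l_locus_fraction` | 0.30 / 0.10 | sample-level unstable-locus fractions (≥, i.e. ties count) |
| `fga_log2_threshold` | 0.3 | a segment is altered when \|log2 ratio\| strictly exceeds this |
| `fga_cnh_threshold` | 0.2 | FGA at or above this triggers CNH under `tp53_or_fga` |
| `cn_rule` | `tp53_or_fga` | CNH if TP53-mutant or genome-altered; `tp53_only` available |
| `panel_size_mb` | 1.0 | TMB denominator |

TMB counts nonsynonymous variants (missense, nonsense, frameshift,
splice, in-frame indel) passing the VAF filter, per megabase. The POLE
hotspot list ships with the eleven recurrent exonuclease-domain variants
with established ultramutator phenotype (P286R, V411L, S297F, S459F,
A456P, F367S, L424I, M295R, P436R, M444K, D368Y); it is a config field,
not a constant.

**MSI surrogate.** Commercial panel MSI callers are proprietary. The
per-locus score here is deliberately minimal and fully reproducible: the
fraction of tumor reads at repeat lengths essentially unsupported by the
baseline distribution (probability < `baseline_support_floor`), with the
locus unstable when that fraction strictly exceeds `msi_novel_length_tau`.
It is invariant to read-depth rescaling by construction. Tie-breaks are
deliberate and tested: strict `>` at the locus level, `≥` at the
sample-level fractions. Loci with zero reads are excluded from the
denominator with a warning; a sample with no scoreable locus is not
evaluable for MSI.

**Copy-number surrogate.** The upstream study's CN algorithm is
unpublished ("in-house"). Because CNL is described as the TP53-wild-type
group and CNH as TP53-mutant/serous-like, the default rule is
TP53-driven with an FGA clause: CNH iff TP53 is mutated or the
length-weighted fraction of covered bases in altered segments (FGA) is at
least 0.2. `tp53_only` reproduces a pure p53-surrogate classification.

## Survival statistics

Kaplan–Meier estimation and the k-group log-rank test are delegated to
lifelines; confidence bands are Greenwood-based on the log(−log) scale.
`curve_summary` defines the horizon rate as S at the last event time at
or before the horizon (1.0 if none; 10-year horizon = 120 months) and
the median as the smallest event time with S ≤ 0.5, reported as
not-reached otherwise. Times are months throughout.

Cox models maximize the partial likelihood with Efron tie handling by
default (Breslow by flag, via statsmodels PHReg). The Efron path uses
lifelines' damped Newton iteration with progressively smaller step sizes
(1 → 0.25 → 0.1): undamped quasi-Newton steps can diverge to absurd
coefficients when an effect is strong and events are sparse (the CNH
indicator in heavily censored cohorts reliably triggers this), and the
divergence is otherwise silent. A fit whose coefficients are non-finite
or implausibly large (|log HR| ≥ 50) is returned with
`converged=False` and an all-NaN table — never a quietly wrong number.
Wald 95% CIs and p-values are reported per covariate. For the
study-style multivariate OS model the covariate coding is: age
dichotomized at 55; stage I–II vs III–IV; LVSI yes/no; subtype
indicators against the CNL reference (largest group). No
multiple-testing correction is applied anywhere.

## Concordance

Accuracy is observed agreement; Cohen's kappa corrects it by the chance
agreement of the marginal label distributions, defined as 1 in the
degenerate identical-constant case. Confidence intervals are percentile
bootstrap (2.5/97.5) over paired resamples, 1000 by default, from a
single seeded generator; resampling is by sample index, so input order
affects the exact draws (documented, and irrelevant to the point
estimates, which are order-invariant). BCa corrections are out of scope.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws subtypes at the observed study proportions
(19/44/27/143 of 233) and gives each sample markers that are
*unambiguous* for its planted label: POLE samples carry p.P286R; MSI-H
samples are hypermutated (log-normal TMB, median 40 mut/Mb, σ=0.35)
with a 0.4–0.8 unstable-locus fraction over 25 loci; CNH samples are
TP53-mutant with FGA ≈ 0.5; CNL samples are TP53-wild-type with a quiet
genome (POLE TMB median 200, CN groups 5). Overall survival is
exponential per subtype, calibrated so the CNH median is 35 months and
the POLE 120-month survival is 0.99 (MSI-H 0.80, CNL 0.85 at 120
months), censored by a uniform 7–122-month administrative window
(median follow-up ≈ 66 months). ARID1A and ZFHX4 mutations are planted
with CNL/MSI-H-enriched prevalences and hazard ratios 2 and 3
(multiplicative on the subtype hazard). A Weibull shape parameter is
exposed for sensitivity checks; all randomness flows from one seeded
`numpy` generator.

Because markers are generated unambiguously, near-perfect label
recovery on synthetic cohorts demonstrates that the *decision logic* is
correct — not that the thresholds would perform equally on real panel
data, where VAF noise, subclonality, borderline MSI and intermediate
FGA blur the margins. Clinical covariates are drawn independently of
subtype (only age depends on it), so synthetic data cannot exercise
confounding between stage and subtype.

Two exact fixtures are built programmatically: `table1` (233 samples
whose subtype labels and stage/LVSI/histology/grade cross-tabs match the
printed characteristics table cell-for-cell, with minimal molecular
layers that re-classify to the assigned labels; ages and survival times
are synthetic, matching only group-level structure: 131 with OS, 126
with DSS) and `fig4` (the 39-sample CNL/MSI-H wide-panel subset). The
fig4 deceased/surviving split and per-group mutation counts
(13/26; ARID1A 7/8; ZFHX4 4/0) are the unique integer solution to the
printed one-decimal percentages given that all four ZFHX4 mutations
occurred in deceased cases — the uniqueness is verified by exhaustive
search in the test suite before the constants are trusted.

## Numerical and formatting choices

Percentages in cohort summaries are rounded half-up (`Decimal`), always
against the full cohort denominator, matching how clinical tables report
explicit "unknown" rows; biomarker frequencies are one-decimal
percentages. Variant positions are 1-based (VCF), copy-number segments
0-based half-open (BED). TSV floats are serialized with `repr` so a
write/read round trip is bit-identical. Empty cohorts summarize to zero
counts and 0.00 percentages rather than erroring.

## Problem sizes used by the checked examples

The statistical checks in the test suite use: 2000 null replicates of
n=200 for log-rank type-I error; n=2000 with ~20% censoring for Cox
effect recovery (±0.1 on log HR ln 2); n=1000 synthetic samples for
end-to-end label recovery (≥99%); 500 replicates of n=300 rater pairs
with 1000 bootstrap draws each for kappa CI coverage (the percentile
bootstrap is visibly anti-conservative below n≈200, so calibration is
assessed where the method is intended to operate); 200 seeds for the
multinomial subtype-count expectation. All seeds are fixed in the tests.

## Known limitations

* The MSI and copy-number callers are documented surrogates, not
  reconstructions of the proprietary panel pipeline; their thresholds
  are conventional, not fitted.
* The study-scale survival quantities (per-subtype hazard rates, Cox
  HRs) depend on patient-level data that are not public; the package
  reproduces the *methods* and the printed compositional/subgroup
  numbers, and validates the statistics by simulation instead.
* Germline filtering, signature-based POLE calling, FASTQ/BAM
  processing and plot rendering are out of scope.
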