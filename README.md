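# ecsubtype

Molecular subtyping of endometrial carcinoma (EC) from a single targeted
NGS panel, with the downstream survival and biomarker analyses that make
the subtypes clinically useful.

EC splits into four prognostic molecular groups — **POLE**
(ultramutated), **MSI-H** (hypermutated/microsatellite-unstable), **CNH**
(copy-number high, TP53-mutant/serous-like) and **CNL** (copy-number low,
TP53-wild-type) — classically assigned by combining immunohistochemistry
with sequencing. `ecsubtype` implements a one-assay alternative: every
marker is derived from one panel's output, and samples are labeled by a
strict hierarchy

```
POLE pathogenic variant?  ──yes──▶ POLE
        │ no
MSI-H and hypermutated?   ──yes──▶ MSI-H
        │ no  (MSI-L and MSS treated alike)
TP53 mutated or FGA ≥ 0.2? ─yes──▶ CNH,  else ▶ CNL
```

with TMB = nonsynonymous variants / Mb after a ≥5% VAF filter, per-locus
MSI instability scored as the fraction of reads at repeat lengths
unsupported by the baseline histogram, and FGA the length-weighted
fraction of covered bases with |log2 ratio| > 0.3. The package also
provides Kaplan–Meier / log-rank / Cox survival stratification, accuracy
and Cohen's κ with percentile-bootstrap CIs for classifier concordance,
ARID1A/ZFHX4 sub-stratification of CNL/MSI-H tumors, a fully seeded
synthetic cohort generator, and exact 233-sample / 39-sample reference
cohorts rebuilt from published summary tables. See `docs/methods.md` for
the model details and every tunable threshold.

Intended users: bioinformaticians validating simplified NGS-based EC
classifiers, and anyone needing a reproducible, testable reference
implementation of the POLE → MSI-H → CNH/CNL decision rule.

## Worked example

```python
import ecsubtype as ec

cohort = ec.load_fixture("table1")            # 233-sample reference cohort
labels = ec.classify_cohort(cohort)           # markers + hierarchy per sample
summary = ec.summarize_cohort(cohort, {k: v.value for k, v in labels.items()})
print("n =", summary.n_total)
for subtype in ("POLE", "MSI-H", "CNH", "CNL"):
    print(f"{subtype:6s} {summary.counts[subtype]:4d}  {summary.percentages[subtype]:6.2f}%")

fig4 = ec.load_fixture("fig4")                # 39 CNL/MSI-H wide-panel samples
mm = ec.build_mutation_matrix(fig4)
vital = {s.sample_id: s.clinical.vital_status for s in fig4}
freqs = ec.mutation_frequencies_by_outcome(mm, vital)
print(freqs.loc[["ARID1A", "ZFHX4"], ["freq_deceased", "freq_surviving"]])
res = ec.km_by_mutation(fig4, mm, "ZFHX4")
print("log-rank p = %.2g" % res.logrank.p_value)
```

prints

```
n = 233
POLE     19    8.15%
MSI-H    44   18.88%
CNH      27   11.59%
CNL     143   61.37%
        freq_deceased  freq_surviving
ARID1A           53.8            30.8
ZFHX4            30.8             0.0
log-rank p = 0.00042
```

i.e. classifying the reference cohort from its molecular layers
reproduces the published subtype composition exactly; in the wide-panel
subset, ARID1A mutations are enriched in deceased patients (53.8% vs
30.8%) and all ZFHX4 mutations occur in deceased patients (30.8% vs 0%),
with a significant survival split for ZFHX4 carriers.

The same flow is available from the shell:

```bash
ecsubtype simulate --n 233 --seed 7 --out sim/
ecsubtype classify --variants sim/variants.tsv --msi sim/msi.tsv \
    --segments sim/segments.tsv --clinical sim/clinical.tsv --out cls/
ecsubtype survival --labels sim/truth_labels.tsv --clinical sim/clinical.tsv --out surv/
ecsubtype concordance --labels-a cls/subtypes.tsv --labels-b sim/truth_labels.tsv \
    --n-boot 1000 --seed 17 --out conc/
```

Exit codes: 0 success, 1 validation failure, 2 usage error; every output
directory gets a `manifest.json` with the command, config hash, seeds
and package version.

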