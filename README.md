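# organodx

Analysis pipeline for oxaliplatin-response studies in colorectal-cancer
patient-derived organoids (PDOs): quantify in vitro drug response, score in
vivo xenograft efficacy, discover transcriptomic response-predictor
signatures, select candidate sensitizer drugs by connectivity scoring, and
test concordance between organoid calls and patient outcomes.

It is written for translational researchers running organoid drug screens
who want the full chain — viability plate → response class → signature →
drug candidate → clinical validation statistics — as tested, scriptable
components rather than spreadsheet steps.

## What it computes

**Dose response.** Viability `V(d)` over an 8-dose oxaliplatin grid
(0.03–100 µM, four replicates) is fitted with the four-parameter logistic

    V(d) = bottom + (top − bottom) / (1 + (d / IC50)^h)

giving potency (IC50), efficacy (Emax = % inhibition at 100 µM) and a
normalized AUC. PDOs are classified on log₁₀IC50 into strong
(0.14–0.57), moderate (0.57–0.98), minor (0.98–1.24) and non-responders
(1.24–2.00); strong+moderate form the oxaliplatin-sensitive (OS) group,
minor+non the resistant (OR) group. Combination-therapy shifts are reported
as relative IC50 (orders of magnitude) and ΔEmax.

**Xenograft efficacy.** From paired control/treated arm medians,

    %TGI = {[1 − (T_t/T₀)/(C_t/C₀)] / [1 − C₀/C_t]} × 100

with ≥ 50% defining an in vivo responder.

**Signature discovery.** Counts are normalized by median-of-ratios size
factors; differential expression between OR and OS uses a Wald-type t on
log₂ normalized counts with Benjamini–Hochberg adjustment. Leaving out one
sample at a time yields n ranked lists; the top-100 differentially expressed
features (fold change ≥ 2, adjusted p < 0.05) per fold are intersected into
a consensus signature. Each consensus feature is then scored as a
single-gene logistic-regression predictor by leave-one-out accuracy, with a
seven-classifier validation panel.

**Connectivity.** The consensus up/down sets are scored against reference
rank profiles with the signed Kolmogorov–Smirnov connectivity statistic,
normalized to ±100; perturbagens scoring ≤ −95 in two independent query
routes are intersected into a candidate sensitizer list.

**Clinical concordance.** PDO class vs patient outcome collapses to a 2×2
table: sensitivity/specificity/PPV/NPV/accuracy, two-sided Fisher's exact
test, and a one-sided Cochran–Armitage trend test across the four ordered
response categories.

A synthetic-data module generates every input stream with the matching
statistical structure (4PL plates, negative-binomial 8-vs-8 count matrices
with planted effects, exponential xenograft growth, a 17-patient cohort),
so the whole pipeline runs and is tested without any external data.

## Worked example

```python
import organodx as ox

scen = ox.ScreenScenario(fourpl_truth=((100, 10, 1.2, 3.0),), noise_sd=0.0, seed=1)
fit = ox.fit_4pl(ox.gen_dose_plate(scen, 0))
call = ox.classify_response(fit.log10_ic50)
print(f"IC50 {fit.ic50:.2f} uM  Emax {fit.emax:.1f}%  AUC {fit.auc:.3f}  "
      f"-> {call.category} ({call.group})")

table = ox.Cohort2x2(a=7, b=2, c=3, d=5)   # OS/OR PDOs vs patient response
m = ox.confusion_metrics(table)
print(f"sensitivity {m['sensitivity_pct']:.1f}%  specificity {m['specificity_pct']:.1f}%  "
      f"accuracy {m['accuracy_pct']:.1f}%  Fisher p {ox.fisher_exact(table):.4f}")
```

prints

```
IC50 3.00 uM  Emax 88.7%  AUC 0.610  -> strong (OS)
sensitivity 70.0%  specificity 71.4%  accuracy 70.6%  Fisher p 0.1534
```

The fitted IC50 of 3 µM recovers the generator's ground truth exactly
(noiseless plate); log₁₀(3) = 0.48 falls in the strong-responder interval,
hence OS. The cohort table yields 12/17 correct calls (70.6%); the Fisher p
of 0.15 shows the association alone is not significant at this cohort size,
while the trend of recurrence across ordered categories is
(`ox.cochran_armitage`, one-sided p = 0.047).

An end-to-end synthetic run:

```bash
organodx run --config config.json     # {} gives the fully defaulted pipeline
```

writes per-stage artifacts (fits.csv, tgi.json, consensus.json,
candidates.csv, concordance.json) plus summary.json and a run log.

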