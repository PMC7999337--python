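# svconcord

Concordance analysis and clinical benchmarking for structural-variant
(SV) callsets from two exome sequencing platforms, built for the setting
where the same multiple-myeloma (MM) samples have been sequenced by both
standard whole-exome sequencing (WES) and linked-read exome sequencing,
SVs called with Manta, and the clinic has FISH results to serve as a
gold standard.

The package answers four questions a molecular-diagnostics group asks of
such data:

1. **How concordant are the two callsets?** Same-type calls match under
   the *reciprocal overlap* rule: intervals *a*, *b* agree when
   |a∩b|/|a| ≥ F and |a∩b|/|b| ≥ F (default F = 0.70, the bedtools
   `-f 0.70 -r` convention). Translocations, which have no end position,
   are assembled from mutually `MATEID`-referencing breakend (BND)
   record pairs and matched separately by chromosome pair and
   per-breakend distance.
2. **Does either platform detect the clinically assayed cytogenetic
   events?** The ten-event MM panel — del(1p), gain(1q), del(13q),
   del(14q), del(17p) and the IGH translocations t(4;14), t(6;14),
   t(11;14), t(14;16), t(14;20) — is scored per sample as counts of
   supporting quality-passing calls (DEL/DUP calls overlapping the
   chromosome arm; assembled breakend pairs joining the partner
   chromosomes).
3. **How well do those scores predict the FISH truth?** Sweeping a
   threshold *t* over the support scores yields sensitivity TP/P and
   specificity TN/N at each *t*, the ROC curve, and the trapezoid AUC
   (equivalently the Mann–Whitney probability
   P(score₊ > score₋) + ½·P(tie)), with a percentile-bootstrap
   confidence interval.
4. **What is each sample's SV-hotspot burden?** Calls are annotated
   against a catalog of published MM hotspot regions (gain / loss /
   fragile), counting each hotspot once per sample, with cohort medians.

A somatic short-variant filter cascade (caller filters → region class →
exonic function → population AF ≤ 1% → QUAL ≥ 40 → depth ≥ 10 →
VAF ∈ [2%, 30%] → strand-odds-ratio ≤ 3 for SNVs / ≤ 11 for indels),
three-way dataset overlaps, and an MM driver-gene matrix
(BRAF/KRAS/NRAS/TP53/FAM46C) round out the analysis. A synthetic-data
module generates Manta-dialect VCF callsets with the two platforms'
published type compositions (WES-like: 56.3% DEL, 32.6% INS, 6.7% BND,
3.3% DUP, 1.2% INV; linked-read-like: 92.4% INV, no INS) and plants
panel events with configurable detection sensitivity, so the entire
pipeline runs and validates without patient data.

## Worked example

Simulate an eight-sample cohort with both platform profiles, score the
clinical panel, and benchmark against the planted truth:

```python
import pandas as pd
from svconcord import (build_event_panel, detect_events, roc_curve,
                       default_profiles, generate_callset, simulate_truth)
from svconcord.cytogenetics import PredictionMatrix
from svconcord.synthetic import synthetic_arm_map

arms = synthetic_arm_map()                     # 22-chromosome p/q arm model
panel = build_event_panel(arms)                # the 10 clinical events
truth, _ = simulate_truth(8, panel, seed=11)   # FISH-style 0/1 labels
print("positive cells:", truth.P, "of", truth.P + truth.N)

profiles = default_profiles()
sens = {"wes_like": 0.9, "linkedread_like": 0.5}
for method, profile in profiles.items():
    rows = {}
    for i, sample in enumerate(truth.samples):
        cs = generate_callset(profile, truth.table.loc[sample].to_dict(),
                              sens[method], arms, seed=100 + i,
                              sample=sample, method=method, panel=panel)
        rows[sample] = detect_events(cs, panel)   # PASS-only support counts
    pred = PredictionMatrix(pd.DataFrame.from_dict(rows, orient="index"), method)
    res = roc_curve(pred, truth, n_boot=500, seed=0)
    print(f"{method}: AUC = {res.auc:.3f}  (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
```

Output:

```
positive cells: 22 of 80
wes_like: AUC = 0.867  (95% CI 0.792-0.933)
linkedread_like: AUC = 0.636  (95% CI 0.536-0.753)
```

22 of the 80 (sample, event) cells carry a planted event. The WES-like
platform, given 0.9 detection sensitivity per planted event, separates
positive from negative cells far better than the linked-read-like
platform at 0.5 sensitivity — the score threshold sweep turns per-event
support counts into the ROC curves whose areas are printed with their
bootstrap intervals.

The same stages are available from the shell:

```sh
svconcord simulate --n-samples 8 --seed 7 --out cohort/
svconcord roc --arms cohort/cytoband.tsv --truth cohort/truth.tsv \
    --vcf S01:wes_like:cohort/S01_wes_like.vcf ... --seed 7
svconcord concord --vcf-a a.vcf --vcf-b b.vcf --sample S01 --fraction 0.70
```

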