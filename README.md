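# smpull

Analysis pipeline for single-molecule pull-down (SiMPull) imaging of protein
aggregates in serum, aimed at labs using surface-capture single-molecule
assays as fluid biomarkers for synucleinopathies. It covers the full chain
from raw fluorescence stacks to a cohort-level discriminator:

1. **Counting** — diffraction-limited TIRF stacks are averaged and
   path-connected components above a robust threshold (median + k·1.4826·MAD)
   are counted as aggregate spots, per field of view (FoV), for the
   α-synuclein and amyloid-β channels; per-spot intensities classify
   "high-intensity" spots (>25,000 A.U.).
2. **Morphology** — dSTORM blink stacks (or precomputed localization tables)
   are drift-corrected by redundant cross-correlation, rendered at 20 nm,
   segmented, and each aggregate is measured for perimeter *P* (µm) and
   circularity *C* = 4π·Area/*P*², clipped to 1.
3. **Biomarker** — per sample: the proportion *R* = α/(α+β) of the two mean
   counts; morphology thresholds (*P\**, *C\**) discovered as the argmax of
   the group-averaged cumulative-histogram difference (control − PD); the
   morphologically-distinct fraction *f* = Pr(*P* > *P\** and *C* > *C\**);
   and the combined score *S* = *R*·*f*. Groups are compared with a
   KS-normality-gated Welch / Mann–Whitney test, and each discriminator gets
   a Mann–Whitney AUC with Wilson intervals on sensitivity/specificity at
   the Youden point.

No raw patient data are distributed with the assay, so the package includes
a first-class synthetic-data generator (`smpull.synth`) producing
PSF-convolved camera stacks, blinking-emitter localization streams from
aggregates with analytically known shape, and full two-group cohorts at the
study's printed count statistics — all with ground truth retained for
parameter-recovery testing. See `docs/methods.md` for the models and their
assumptions.

## Worked example

Simulate a study-scale cohort (20 PD / 20 control, 28 diffraction-limited
and 6 dSTORM fields per sample) and run the cohort analysis:

```python
from smpull.synth import CohortSpec, simulate_cohort
from smpull.biomarker import run_cohort_analysis

bundle = simulate_cohort(CohortSpec(seed=7))
result = run_cohort_analysis(bundle.fov_counts, bundle.morphology)
print(result.summary_text())
```

```
Cohort analysis summary
=======================
count_alpha_syn: AUC=0.802 [0.664, 0.941]  sens=0.70 (0.48-0.85)  spec=0.90 (0.70-0.97)  welch_t p=0.0004343
count_abeta: AUC=0.385 [0.210, 0.560]  sens=1.00 (0.84-1.00)  spec=0.05 (0.01-0.24)  welch_t p=0.2494
ratio: AUC=0.838 [0.711, 0.964]  sens=0.90 (0.70-0.97)  spec=0.65 (0.43-0.82)  welch_t p=0.0005081
combined_score: AUC=0.912 [0.818, 1.000]  sens=0.75 (0.53-0.89)  spec=0.95 (0.76-0.99)  welch_t p=6.276e-07
thresholds[alpha_syn]: P*=0.254 um (max diff 5.0%), C*=0.606 (max diff 6.4%)
thresholds[abeta]: P*=0.331 um (max diff 2.4%), C*=0.705 (max diff 4.3%)
No multiple-testing correction applied (prespecified discriminators).
```

Reading the output: the α-syn count alone separates the groups (AUC 0.80,
p < 0.001) while the Aβ count does not (AUC below 0.5 — PD samples carry
slightly *fewer* Aβ aggregates); the count ratio improves on either, and
multiplying it by the fraction of large-and-round α-syn aggregates (here
those with perimeter > 0.25 µm and circularity > 0.61, found from the
cumulative-difference curves) gives the strongest discriminator. PD is the
positive class throughout, so an AUC below 0.5 means the metric favours
controls.

The same chain runs from the shell, end to end or stage by stage:

```bash
smpull run --seed 7 --out report/           # simulate -> detect -> storm -> biomarker
smpull simulate --config examples/cohort.yaml --seed 7 --out cohort/
smpull detect --in cohort/ --out metrics.csv
smpull storm --in cohort/ --out morph.csv
smpull biomarker --metrics metrics.csv --morph morph.csv --out report/
```

`run` writes `cohort_report.csv` (per-sample metrics), `thresholds.csv`,
`roc.csv`, and `summary.txt`, each stamped with the seed and a configuration
hash; reruns with the same configuration are byte-identical.

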