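# wgskit

A library and command-line toolkit implementing the **computerised
paediatric Wisconsin Gait Scale (WGS)**: a machine-encoded version of the
14-item observational gait rubric used to assess children with spastic
hemiplegic cerebral palsy, together with the freeze-frame landmark
geometry that supports each rating and the complete rater-reliability
analysis toolchain used to validate such instruments.

It is aimed at clinical-movement-analysis researchers and physiotherapists
who rate gait videos with the paediatric WGS and want (a) reproducible,
quantitative evidence behind each item rating, and (b) standard
inter-/intra-rater reliability statistics over panels of ratings.

## The scale and its score

The paediatric WGS rates 14 gait features across the gait phases of the
affected leg (stance, toe off, swing, heel strike). Most items are scored
1–3 (1 = best); item 1 (gait-aid use) is scored 1–5 and item 11 (knee
flexion from toe off to mid swing) 1–4, with *a/b* sub-options on items 4
and 11 that qualify *how* a deviation occurs without changing its numeric
severity. The total is a weighted sum

    total = (3/5)·s₁ + (3/4)·s₁₁ + Σ_{i∉{1,11}} s_i ,

so every item contributes at most 3 points and the total spans
**13.35 – 42** (higher = poorer gait). Totals are exact rationals
internally, rounded half-up to two decimals on export.

From annotated video frames (named 2-D landmarks, gait-event frame
indices, a shoe-width pixel calibration) the kinematics module
reconstructs the quantities a rater inspects — knee flexion as the angle
between the thigh line (trochanter – lateral femoral condyle) and the
shank line (fibula head – lateral malleolus), hip extension, stance times,
stance width and circumduction in shoe widths, foot external rotation
against the 45° anchor, toe clearance, and so on — and maps them to
*advisory* option-code suggestions with the numeric evidence attached.

The reliability module implements the analysis plan for validating the
computerised scale: descriptive statistics; the two-way random-effects,
absolute-agreement intraclass correlation (single- or average-measures,
McGraw–Wong convention) with the interpretation bands
poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent; Bland–Altman limits
of agreement (mean difference ± 1.96 SD); Kruskal–Wallis across raters;
Wilcoxon signed-rank test–retest comparisons; and the finite-population
minimum-sample-size formula
Nmin = NP·α²f(1−f) / (NP·e² + α²f(1−f)).

Because no patient ratings or recordings are published, the package ships
synthetic generators (`wgskit.simulate`) that produce rating panels and
landmark gait trials with known ground truth, used throughout the tests.

## Worked example

Simulate one recorded walk (both camera views), measure it, and score it:

```bash
$ wgskit simulate --kind gait --seed 3 --out demo
wrote demo/sagittal.json
wrote demo/frontal.json
$ wgskit score --sagittal demo/sagittal.json --frontal demo/frontal.json \
    --set 1=1 --set 13=1 --out demo
wrote demo/measurements.csv
total score: 13.35
```

The simulated gait is symmetric and deficit-free, so every measurable
item is suggested at code 1 and — with the two observational items (1,
gait-aid use; 13, pelvic rotation) set manually to 1 — the weighted total
is the scale minimum, 13.35. `demo/measurements.csv` lists, per item, the
measurement value, unit, suggested code and a one-line rationale such as
`heel separation 0.80 shoe widths (normal <= 1, moderate <= 2)`.

Reliability analysis of a rating panel (31 participants × 3 raters × 2
sessions, noise-free here, so agreement is perfect):

```bash
$ wgskit simulate --kind panel --seed 2 --out demo
wrote demo/ratings.csv
$ wgskit reliability --ratings demo/ratings.csv --out demo
wrote demo/report.json and 5 tables
75 hypothesis tests performed (no multiplicity correction)
```

`demo/icc.csv` then reports ICC = 1.0 ("excellent") for every item and
the total, and `demo/wilcoxon.csv` shows p = 1.0 for every test–retest
comparison. The sample-size helper:

```bash
$ wgskit samplesize --np 1000 --alpha 1.96 --f 0.5 --e 0.05
278
```

In Python the same pieces are plain functions: `load_rubric()`,
`total_score()`, `measure_trial()`, `suggest_ratings()`,
`icc_two_way_random_absolute()`, `bland_altman()`,
`reliability_report()`, `simulate_panel()`, `simulate_gait()`.

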