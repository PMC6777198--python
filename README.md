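# aortadose

Individualized contrast-agent dosing for CT angiography of the aorta,
and a simulated re-analysis of the three-arm pilot study that evaluated
it.

Fixed contrast doses (historically 120 ml) over-dose small patients and
under-dose large or tachycardic ones, because aortic enhancement scales
with body habitus and circulation. `aortadose` reimplements an
injector-side calculator that individualizes the dose from heart rate
and body surface area (BSA), and provides the simulation and
statistical machinery to re-run the study that compared three arms —
fixed 120 ml, calculator-dosed (40–150 ml), and calculator + 50%
dilution (≥20 ml) — on synthetic cohorts, since the underlying clinical
scans are not available.

## The dose algorithm

For a patient with weight *w* (kg), height *h* (cm), heart rate *HR*
(bpm) and contrast concentration *c* (mg I/ml):

1. **BSA** — as the injector documentation prints it (the default,
   "literal" reading): BSA = (*h* · *w* / 3600) × 0.5.
   The Mosteller reading BSA = √(*h* · *w* / 3600) is available as a
   config switch (`bsa_mode="mosteller"`); only the literal reading
   reproduces the device's documented worked example.
2. **Base dose** — BSA × 45 ml/m².
3. **Heart-rate correction** (ml): ≤55 → −10; 56–65 → 0; 66–75 → +10;
   76–90 → +20; 91–105 → +25; >105 → +30.
4. **Concentration correction** — ±2 ml per 10 mg I/ml below/above the
   350 mg I/ml reference.

The sum is rounded half-up to whole ml and clamped to the protocol
window **40–150 ml**. The dilution arm halves the clamped dose
(half-up, floor **20 ml**). Injection is 4 ml/s plus a 30 ml saline
flush.

## Worked example

The documented extreme case — 115 kg, 185 cm, 122 bpm at 350 mg I/ml:

```bash
$ aortadose dose --weight 115 --height 185 --hr 122
BSA (literal):            2.9549 m²
Base dose (45 ml/m²):      132.97 ml
Heart-rate correction:     +30 ml
Concentration correction:  +0.0 ml
Raw dose:                  162.97 ml -> 163 ml
Clamped dose [40, 150]:    150 ml
Administered dose:         150 ml
Injection: 4 ml/s + 30 ml saline flush
```

163 ml is pre-calculated; the protocol caps the administered dose at
150 ml.

## The simulated study

`analysis/` holds the numbered drivers (run them in order from the
repository root; outputs land in `results/`):

| script | what it does |
|---|---|
| `00_calibrate_scores.py` | fits the HU → latent-quality score map to the published arm-mean scores 4.5/4.6/3.7 |
| `01_simulate_cohorts.py` | samples the three arms (n = 20) from truncated normals with the published demographics |
| `02_calculate_doses.py`  | runs the calculator per arm; simulated arm means 120.0 / 100.3 / 48.1 ml vs published 120 / 101.8 / 48.1 ml |
| `03_simulate_imaging.py` | draws five-level enhancement records and two-reader 1–5 scores |
| `04_phantom_roundtrip.py`| renders aneurysm/thrombus/dissection phantoms and shows the circular-ROI measurement is an unbiased round trip |
| `05_analyze_study.py`    | descriptives, pooled-t comparisons at α = 0.025, percent differences, inter-/intra-observer ICC(C,k) |

The same pipeline is scriptable end to end
(`aortadose simulate --seed 0 --out run/`) and fully deterministic per
seed. A single default run reproduces the study's qualitative result:
the calculator arm cuts the dose by ~15% with unchanged enhancement and
scores, the dilution arm by ~60% with markedly lower enhancement and
acceptable-but-reduced scores.

## Scope

Acquisition physics (collimation, kV/mAs, bolus tracking), radiation
dosimetry, DICOM handling and injector-hardware protocols are out of
scope. The phantom is a flat 2-D stand-in for measurement geometry, not
a CT simulator.
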