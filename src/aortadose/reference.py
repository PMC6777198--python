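"""Published summary values of the three-arm pilot study.

These are inputs for comparison and calibration — the per-arm summary
table of the study this package re-analyses in simulation.  Nothing in
the simulation pipeline reads them at run time except as calibration
targets and reporting baselines.
"""

from __future__ import annotations

#: Per-arm contrast dose (ml): mean, sd. The control arm is fixed at 120 ml.
PUBLISHED_DOSE = {
    "standard": {"mean": 120.0, "sd": 0.0, "min": 120.0, "max": 120.0},
    "calculator": {"mean": 101.8, "sd": 23.2, "median": 102.5, "min": 42.0, "max": 150.0},
    "calculator_diluted": {"mean": 48.1, "sd": 12.2, "median": 46.0, "min": 29.0, "max": 72.0},
}

#: Per-arm mean aortic enhancement (HU) over the five measurement levels.
PUBLISHED_ENHANCEMENT = {
    "standard": {"mean": 282.2, "sd": 82.1, "median": 284.5, "min": 156.3, "max": 569.8},
    "calculator": {"mean": 279.3, "sd": 68.7, "median": 284.5, "min": 155.6, "max": 421.3},
    "calculator_diluted": {"mean": 191.2, "sd": 79.3, "median": 191.5, "min": 79.1, "max": 449.1},
}

#: Per-arm reader-averaged visual score (1–5 scale).
PUBLISHED_SCORE = {
    "standard": {"mean": 4.5},
    "calculator": {"mean": 4.6},
    "calculator_diluted": {"mean": 3.7},
}

#: Reported agreement coefficients (ICC, consistency, average measures).
PUBLISHED_ICC = {"inter_observer": 0.472, "intra_observer": 0.601}

#: Arm sizes of the published study.
PUBLISHED_GROUP_SIZES = {"standard": 20, "calculator": 20, "calculator_diluted": 20}
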