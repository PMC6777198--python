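#!/usr/bin/env python
"""Calibrate the HU → latent-quality score map.

Fits the intercept and slope of the linear map from mean aortic
enhancement to the latent 1–5 quality score so that the analytic
reader-averaged expected score per arm reproduces the published group
means (4.5 / 4.6 / 3.7) under the default reader-noise and reader-2 bias
settings.  The fitted coefficients are frozen into the package defaults
(``SimulationConfig``); this script documents and reproduces that fit.
"""

import json
from dataclasses import replace
from pathlib import Path

from aortadose.imaging import SimulationConfig, calibrate_score_map, expected_group_scores
from aortadose.reference import PUBLISHED_SCORE

OUT = Path("results")


def main() -> None:
    intercept, slope = calibrate_score_map()
    fitted = replace(SimulationConfig(), score_intercept=intercept, score_slope=slope)
    expected = expected_group_scores(fitted)
    frozen = expected_group_scores(SimulationConfig())

    print(f"fitted score map: latent = {intercept:.4f} + {slope:.6f} × mean_HU")
    print(f"{'arm':<22}{'target':>8}{'fitted':>9}{'frozen default':>16}")
    for g, pub in PUBLISHED_SCORE.items():
        print(f"{g:<22}{pub['mean']:>8.2f}{expected[g]:>9.3f}{frozen[g]:>16.3f}")
    print(
        "Arms 1 and 2 have nearly identical enhancement distributions, so a "
        "monotone HU→quality map cannot separate their scores further; both "
        "land at the midpoint ≈4.55, within 0.06 of their targets."
    )

    OUT.mkdir(exist_ok=True)
    (OUT / "score_calibration.json").write_text(
        json.dumps(
            {
                "intercept": intercept,
                "slope": slope,
                "expected_scores": expected,
                "targets": {g: v["mean"] for g, v in PUBLISHED_SCORE.items()},
            },
            indent=2,
        )
    )
    print(f"wrote {OUT / 'score_calibration.json'}")


if __name__ == "__main__":
    main()
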