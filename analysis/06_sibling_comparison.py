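"""Sibling-subsample analysis with IPW and within-family adjustment.

Estimates stabilised inverse-probability weights for selection into the
sibling subsample, decomposes each exposure into family mean and child
deviation, and contrasts unadjusted with family-confounding-adjusted
effects on the differentiation growth factors.  Attenuation of an estimate
after adjustment points to familial confounding (or, for exposures that
barely vary within families, to an unreliable within estimate).
"""

import json
import pathlib

import pandas as pd

from diffgrowth.siblings import estimate_sibling_weights, fit_sibling_models
from diffgrowth.simulate import EXPOSURE_COLS

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

scored = pd.read_csv(OUT / "scored.csv")

wv = estimate_sibling_weights(scored, exposures=tuple(EXPOSURE_COLS))
print(f"IPW: {len(wv.weights)} sibling children, "
      f"{wv.truncated} weights truncated at {wv.truncation_threshold:.2f}, "
      f"min propensity {wv.min_propensity:.3f}")

tab, fits = fit_sibling_models(scored, tuple(EXPOSURE_COLS), weights=wv)
active = tab[tab.exposure.isin([f"x_{j}" for j in range(1, 7)])]
print("unadjusted vs within-family adjusted effects (x_1..x_6 carry real "
      "differentiation effects in the default calibration):")
print(active[["exposure", "factor", "beta_unadjusted", "beta_adjusted",
              "attenuation", "within_share"]].round(3).to_string(index=False))

tab.to_csv(OUT / "sibling_effects.csv", index=False)
with open(OUT / "weights_report.json", "w") as fh:
    json.dump({"n_weights": len(wv.weights), "truncated": wv.truncated,
               "truncation_threshold": wv.truncation_threshold,
               "min_propensity": wv.min_propensity,
               "n_low_overlap": wv.n_low_overlap}, fh, indent=2)
print(f"wrote sibling_effects.csv and weights_report.json under {OUT}")
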