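"""Train the 4-16-1 sound-speed network on a synthetic databank.

The generator emulates the published modelling conditions: 38 DESs, 11
temperatures each (293.15-343.15 K), descriptors inside the published
min-max boxes, and 1 m/s Gaussian measurement noise.  Training is
Levenberg-Marquardt on min-max-scaled data with a seeded 300/115-style
random split.
"""

import dessound as ds

df = ds.generate_synthetic(ds.SyntheticConfig(seed=42))
print(f"synthetic databank: {len(df)} points, "
      f"u in [{df.u_ms.min():.0f}, {df.u_ms.max():.0f}] m/s")

model, report = ds.train(df, ds.TrainingConfig(seed=42))
for rep in (report.train_metrics, report.test_metrics):
    print(f"{rep.label:5s}  n={rep.n:3d}  ARD%={rep.ard_percent:.3f}  "
          f"RMSE={rep.rmse:.2f} m/s  MAE={rep.mae:.2f} m/s  R2={rep.r2:.5f}")

ds.save_model(model, "sound_speed_model.json")
print("\nsaved to sound_speed_model.json;")
print("test-set ARD% well below 0.1% means the network recovers the data-")
print("generating surface to within the injected measurement noise.")
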