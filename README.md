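# dessound

Predicting the speed of sound *u* of deep eutectic solvents (DESs) from
molecular structure alone, for solvent designers who need second-order
thermodynamic properties before any experimental data exists.

A DES — a hydrogen-bond acceptor (HBA) and donor (HBD) mixed at a molar
ratio a:b — is treated as a **pseudo-pure component**: its functional-group
counts, atom count and molecular weight are mole-fraction blends of the two
components' values with x<sub>HBA</sub> = a/(a+b). Joback–Reid-type group
increments (with Valderrama-style ion groups for quaternary nitrogen and
halide anions) then give the pseudo-critical properties

- T<sub>b</sub> = 198 + Σ<sub>k</sub> N<sub>k</sub> tb<sub>k</sub>  [K]
- T<sub>c</sub> = T<sub>b</sub> / (0.584 + 0.965 S − S²), S = Σ<sub>k</sub> N<sub>k</sub> tc<sub>k</sub>  [K]
- P<sub>c</sub> = (0.113 + 0.0032 N<sub>atoms</sub> − Σ<sub>k</sub> N<sub>k</sub> pc<sub>k</sub>)<sup>−2</sup>  [bar]
- V<sub>c</sub> = 17.5 + Σ<sub>k</sub> N<sub>k</sub> vc<sub>k</sub>  [cm³/mol]
- ω from T<sub>b</sub>, T<sub>c</sub>, P<sub>c</sub> via a base-10 logarithmic
  closed form referenced to P<sub>b</sub> = 1.01325 bar.

Four descriptors — T, V<sub>c</sub>, ω, MW — feed a 4–16–1 feedforward
network with tansig (≡ tanh) hidden units and a linear output,

u = σ<sub>y</sub><sup>−1</sup>( b<sup>o</sup> + Σ<sub>j</sub> w<sub>j</sub><sup>ho</sup> · tanh( Σ<sub>i</sub> w<sub>ji</sub><sup>ih</sup> p<sub>i</sub> + b<sub>j</sub><sup>h</sup> ) ),

min–max scaled to [−1, 1] and trained by Levenberg–Marquardt (damped
Gauss–Newton on the full Jacobian). Around the model sit the field's
standard evaluation and reliability tools: ARD%/RMSE/SD/MAE/R² metrics,
dataset summary statistics, cumulative-frequency curves, Williams-plot
leverage screening of the applicability domain (h* = 3(n+1)/m), and Garson
weight-partitioning sensitivity of the four inputs.

The package bundles checksum-pinned transcriptions of the published
group-increment table, the 38-DES pseudo-critical-property table and the
published 16-neuron weight matrix, plus a seeded synthetic-databank
generator that emulates the published modelling conditions (the literature
sound-speed databank itself is not redistributable).

## Worked example

```python
import dessound as ds

components = ds.load_components()
props = ds.estimate_des(components["choline_chloride"],
                        components["ethylene_glycol"], 1, 2)  # "ethaline"
print(props.tc, props.vc, props.mw)
```

Running `python examples/critical_properties.py` prints

```
DES        Tb/K     Tc/K  Tc(pub)   dev%      Vc   omega      MW
DES22    437.58   601.05   602.00  -0.16   263.5  0.9647   87.92
DES23    513.99   676.01   680.67  -0.69   309.5  1.3391  107.93
DES26    452.54   617.10   620.93  -0.62   281.5  1.0025   91.97
DES36    479.24   653.97   654.33  -0.06   362.5  0.8843  109.17
```

i.e. for the DESs fully covered by the bundled group table the estimated
critical temperature lands within 0.7% of the published values; V<sub>c</sub>,
ω and MW are the structure-derived descriptors the network consumes.
(The published P<sub>c</sub> column cannot be regenerated from the printed
closed form under any fixed increment table — see `docs/methods.md` for the
analysis; ω inherits that discrepancy.)

Training on the emulated databank (`python examples/train_sound_speed.py`):

```
synthetic databank: 418 points, u in [1439, 1824] m/s
train  n=302  ARD%=0.033  RMSE=0.71 m/s  MAE=0.55 m/s  R2=0.99992
test   n=116  ARD%=0.064  RMSE=1.34 m/s  MAE=1.07 m/s  R2=0.99972
```

so with 1 m/s measurement noise the network recovers the data-generating
surface down to the noise floor. `examples/applicability_domain.py` and
`examples/sensitivity_analysis.py` demonstrate the Williams screen and the
Garson importances; on the bundled published weight matrix the four inputs
score V<sub>c</sub> 23.99%, ω 26.38%, MW 28.51%, T 21.12% — every input
matters, none dominates.

A thin CLI wraps the same functions:

```sh
dessound gc-props --des examples/des22.yaml
dessound simulate --seed 1 --out databank.csv
dessound train --data databank.csv --hidden 16 --seed 42 --out model.json
dessound predict --model model.json --des examples/des22.yaml --temps 293.15:343.15:5
dessound evaluate --model model.json --data databank.csv --report report.json
dessound williams --model model.json --data databank.csv --out williams.csv
dessound sensitivity
```

## Layout

- `src/dessound/groups.py` — group-contribution pseudo-critical estimator
- `src/dessound/network.py` — scaling, forward pass, LM training, serialization
- `src/dessound/metrics.py` — error metrics, dataset summary, cumulative frequency
- `src/dessound/diagnostics.py` — leverage/Williams screen, Garson sensitivity
- `src/dessound/data.py` — bundled tables, synthetic generator, dataset IO
- `src/dessound/cli.py` — the `dessound` command
- `docs/methods.md` — model assumptions, parameter choices, known limitations
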