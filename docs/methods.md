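# Methods

## Scope and model

`dessound` estimates the speed of sound u(T) of a deep eutectic solvent
from its molecular structure in two stages: a group-contribution (GC)
estimator that turns HBA/HBD group decompositions plus the molar ratio into
pseudo-critical descriptors, and a small feedforward network that maps
(T, V_c, omega, MW) to u. Everything downstream of the network — metrics,
cumulative-frequency curves, leverage screening, Garson sensitivity — is
the standard QSPR reliability toolkit, implemented on the conventions of
this literature.

## Pseudo-component blending

The DES at molar ratio a:b is modelled as a single pseudo-pure component
whose group counts, atom count and molecular weight are linear blends with
x_HBA = a/(a+b). Blending counts (rather than blending the finished
pure-component properties) is the established convention for
Valderrama-style DES property estimation, and for the checkable DESs it
reproduces the published critical temperatures noticeably better
(e.g. 0.16% vs 1.05% deviation for the 1:2 choline chloride : ethylene
glycol system). Fractional group counts and a fractional atom count are a
deliberate consequence; every equation accepts reals. Ternary mixtures
(e.g. hydrated DESs) are out of scope for the blend; the ratio parser
rejects `a:b:c`.

## GC equations and the increment table

The chain is

    T_b = 198 + sum_k N_k tb_k                                 [K]
    T_c = T_b / (0.584 + 0.965 S - S^2),  S = sum_k N_k tc_k   [K]
    P_c = (0.113 + 0.0032 N_atoms - sum_k N_k pc_k)^-2         [bar]
    V_c = 17.5 + sum_k N_k vc_k                                [cm^3/mol]
    omega = f(T_b, T_c, P_c; P_b)  (base-10 logs, P_b = 1.01325 bar)

with hard errors (never NaNs) when a denominator or bracket leaves its
validity range. The T_c denominator uses the *squared tc-increment sum*;
the typeset source fuses columns and squares the tb sum, which is
dimensionally impossible and diverges, so the standard Joback form is used.
The reference pressure P_b in the acentric-factor form is not stated in the
source; standard atmosphere is the default and it is configurable. Setting
P_c = P_b makes every logarithmic term vanish and forces omega = -1, which
doubles as an exact self-test.

The bundled increment table is a de-garbled transcription: the typeset
source fuses the pc_k and vc_k columns into strings such as "-0.001265"
(pc = -0.0012, vc = 65) or "0.011228" (pc = 0.0112, vc = 28). The split
follows the canonical Joback increments for the organic groups and the ion
convention (quaternary N+, halide anions) for the rest; ring variants carry
a `_ring` suffix. The table ships as CSV with a pinned SHA-256 checksum;
`load_fixture` refuses a silently edited copy. Only groups actually printed
in the source table are bundled — no invented parameters — so components
needing amide, carboxyl or aromatic groups require a user-supplied extended
table.

### Fidelity against the published property table

For the four DESs fully covered by the bundled groups, the chain reproduces
the published T_c to 0.06–0.7% and V_c to 0.9–1.8% (except the
menthol : ethylene glycol system, +13% on V_c). The published P_c column is
**not reproducible**: inverting the P_c closed form against the published
values implies ion-increment sums of −0.048 for one choline chloride DES
and −0.099 for another — mutually inconsistent, so no fixed increment table
can generate that column through the printed equation. The magnitudes are
instead consistent with an MW-dependent modified-Lydersen form
P_c = M/(0.2573 + ΣΔP)² whose increments were not published. omega inherits
the P_c discrepancy through log(P_c/P_b) and is additionally hypersensitive
to T_b near the (T_c − T_b) pole. The acceptance tests assert all four
properties at 2% and the P_c/omega cases fail by design — they are kept
unweakened as a faithful record of the source discrepancy rather than
masked by a looser tolerance.

The 38-row property table bundled for reference carries a derived MW column
(mole-fraction blend of standard formula weights; the source prints none).
It reproduces the published databank-summary MW maximum (190.61) and median
(121.84) exactly, which corroborates the blending convention; the published
minimum (59.39) is not recovered by any reading of the one ternary
hydrated system and the column is treated as provenance only.

## Network

Architecture is fixed by the reference design: 4 inputs, one hidden layer
(default 16 tansig neurons), linear output — 97 free parameters at the
default width. Inputs and target are min–max scaled to [−1, 1]; the scaler
is fitted on the training split only, the convention that makes O(1)
published weight magnitudes plausible. The published weight table contains
hidden and output *weights but no biases*, so it supports the sensitivity
analysis (which needs only weights) but not exact replay of the original
predictions; this package always trains its own models.

Training is Levenberg–Marquardt on the residuals of the scaled targets:
solve (JᵀJ + λI)δ = −Jᵀr with the analytic Jacobian, multiply λ by 10 on a
rejected step and divide by 10 on acceptance (λ ∈ [1e−14, 1e12]), stop on
gradient infinity-norm < 1e−8, relative step < 1e−12 or 400 iterations, and
return the best-so-far parameters with a warning if tolerances were not
met. Weights initialise uniform in [−0.5, 0.5] from the seeded generator;
three seeded restarts are run and the lowest-loss fit kept (the loop is
deterministic for a fixed seed, and the accepted-loss sequence is
non-increasing by construction). The train/test split is a seeded uniform
shuffle with train fraction 300/415, mirroring the reference protocol. A
hand-rolled LM loop is used deliberately — the damping schedule is part of
the specified artifact — and is cross-checked in the tests against
`scipy.optimize.least_squares(method="lm")` from identical starting points.

`neuron_sweep` trains one model per candidate hidden size under a shared
split and seed and picks the test-ARD optimum, breaking ties toward the
smallest size within 1% relative of the best (parsimony). Models serialize
to schema-versioned JSON; Python's shortest-repr floats make the round trip
bit-exact.

## Metrics

ARD%, RMSE, MAE and R² follow the standard definitions (R² in the
coefficient-of-determination form; the typeset source's numerator bar is an
evident typo given its reported R² ≈ 0.998–0.999). SD is implemented
verbatim in this literature's unusual residual²/experimental form, odd
units and all, because the reference tables report it. The dataset summary
reproduces the published descriptive-statistics table's conventions:
population-moment skewness, non-excess kurtosis (normal columns score ≈ 3),
central sum of squares, and sample variance by default with population
variance behind `ddof=0`. Cumulative-frequency curves are right-continuous
empirical CDFs over pointwise ARD%.

## Diagnostics

Leverage uses the design matrix [1, scaled inputs] (p = 5 columns,
consistent with counting n = 4 model inputs in h* = 3(n+1)/m), computed via
thin QR rather than an explicit inverse, with a rank check that rejects
collinear designs. Standardized residuals divide by the sample standard
deviation (ddof = 1) of the raw residuals over the evaluated set — the
source does not define SR, so the simplest convention is used and stated.
Flags partition points into in_domain / high_leverage / outlier / both.
The reference figure quotes h* ≈ 0.0545, which does not equal 3(n+1)/m for
any printed combination of n and m (0.05 for m = 300, 0.0361 for m = 415);
the formula value is reported and the discrepancy left documented rather
than imitated.

Garson importance partitions |w_ih| along each hidden→output path and
multiplies by |w_ho|; the printed variant omits the absolute value on the
output weights, but only the |·| convention can produce the all-positive
21–29% profile reported, so it is the default and the signed variant sits
behind a flag. The result is normalized to sum to one and is invariant to
a common positive rescaling of all weights.

## Synthetic databank

The real 415-point literature databank is not redistributable, so the
generator emulates its published conditions, which are fixed as defaults:
38 DESs × 11 temperatures (293.15–343.15 K, step 5 K → 418 points; the
source says only "a wide range of temperatures"), descriptors drawn
uniformly inside the published min–max boxes (u 1166–2138 m/s,
T_c 602–778.21 K, V_c 146.46–656.4 cm³/mol, ω 0.5139–1.3146,
MW 59.39–190.61 g/mol), and Gaussian noise of sd 1.0 m/s — the stated
standard uncertainty of the experimental sound speeds. Points are allocated
uniformly across DESs (the per-DES counts making up 415 are unpublished).

Two teachers are available. The default analytic surrogate
u = u₀ − b(T−T̄) + c(ω−ω̄) − d·ln(V_c/V̄) + e(MW−M̄) draws its coefficients
from seeded ranges (b ∈ [2,4] m/s/K, c ∈ [150,250], d ∈ [100,180],
e ∈ [0.8,1.5], u₀ = 1652 m/s) chosen once so that the worst-case sum of
term bounds stays inside the published u envelope — generated data is
in-envelope by construction, and u is strictly decreasing in T, matching
the physical trend. The alternative is a seeded random 4–16–1 network
teacher for teacher–student recovery tests (its surface is smooth but not
guaranteed monotone). Everything is reproducible per seed, to the byte in
the written CSV.

What passing tests do and do not show: teacher–student recovery (noise-free
test R² ≥ 0.999, ARD% ≤ 0.1; ARD% ≤ 0.5 at 2 m/s noise) demonstrates that
the pipeline — scaling, LM optimisation, split protocol, metrics — can
extract a 16-neuron surface from ~400 points at realistic noise. It does
not certify accuracy on real DES measurements, whose noise is not i.i.d.
Gaussian, whose descriptors cluster by chemical family rather than filling
the boxes uniformly, and whose u(T) curvature differs between families.

## Numerical choices and degenerate inputs

- tansig is evaluated as `np.tanh` (identical to the printed sigmoid form,
  without overflow for large negative arguments).
- Scaler fitting rejects constant columns; transform→inverse round-trips to
  1e−12.
- `metrics` requires strictly positive experimental values (ARD and SD
  divide by them) and n ≥ 2; the summary requires n ≥ 4 (kurtosis);
  constant summary columns warn and return NaN shape statistics instead of
  crashing.
- Zero residual variance in the Williams screen warns and sets all SR = 0.
- LM handles singular normal equations by damping escalation, never by
  crashing; non-convergence is flagged in the report with best-so-far
  parameters returned.
- Dataset CSVs are written at 12 significant digits; readers address
  columns by name, reject non-positive u with the offending line number,
  and warn on temperatures outside 250–400 K.

## Known limitations

- Binary mixtures only; no SMILES-based automatic decomposition (group
  counts are user input, the field's usual practice for GC methods).
- The bundled group table covers exactly the printed rows; DESs with amide,
  carboxyl, aromatic or sugar chemistry need a user-supplied table.
- Published P_c/omega columns are irreproducible from the printed equations
  (see above); T_c and V_c anchor the validation instead.
- No exact replay of the original network (biases unpublished); the
  bundled weight matrix serves the sensitivity analysis only.
- Training problem sizes used in the tests (up to ~420 points, 16 hidden
  neurons, a few restarts) reflect the reference study's scale; the LM
  loop solves dense normal equations and is not meant for networks orders
  of magnitude larger.
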