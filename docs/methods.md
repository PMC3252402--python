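# Methods

## Pendulum model

The passive measurement pendulum is a rigid compound pendulum whose
fulcrum is the knee joint:

    I θ̈ = −m g L sin θ − sgn(θ̇) μ W r − c θ̇

* `θ` — angular deviation from the hanging equilibrium (rad). The
  anatomical flexion angle at equilibrium (~70° in the mouse knee) never
  enters the dynamics and is carried as metadata.
* `m` — arm mass, default 0.050 kg (the 50 g arm used on mouse limbs,
  about twice body weight).
* `L` — pivot-to-COM distance, default 12 mm. `I` — moment of inertia
  about the pivot, default the slender-arm surrogate `(4/3) m L²`.
* `W` — joint normal load, default `m g`; `r` — effective frictional
  moment arm at the joint, default 1 mm. Only the product `W r` matters
  (verified by a scaling test). These geometric constants are not
  measurable from a publication, so they are calibration inputs shared by
  simulator and estimator; every validation is a round trip through both,
  which makes the results insensitive to the specific values.
* `μ` — Coulomb coefficient of friction, the reported quantity;
  `c` — viscous coefficient, default 0, kept only as a
  model-misspecification probe.
* Release from rest at 12° (protocol: ~12 ± 2°; the study generator draws
  U[10°, 14°] per trial, unit tests pin 12°), sampled at 60 Hz.

Integration is piecewise between velocity zero-crossings (scipy DOP853,
rtol 1e−10, atol 1e−12, terminal event on θ̇) so the friction-torque sign
is exact within each half-cycle; smoothing sgn(θ̇) would curve the decay
the estimator assumes linear. At each turning point the static-stick
condition `|m g L sin θ| ≤ μ W r` is re-evaluated; once it holds, the
angle is frozen. The event states double as an internal oracle for the
exact extrema.

## Why the decay is linear, and the estimator

Energy balance over one half-cycle: the friction torque `μ W r` acts over
a path `θ_n + θ_{n+1}`, while potential energy changes by
`m g L (cos θ_{n+1} − cos θ_n)`. In the small-angle limit this gives a
constant per-half-cycle amplitude decrement

    Δ = 2 μ W r / (m g L)

so OLS of extremum amplitude on half-cycle index has slope −Δ and
`μ̂ = slope · m g L / (2 W r)`. The factor 2 (not 4) is pinned by fitting
*half*-cycles, i.e. successive extrema. At a 12° release the small-angle
approximation biases μ̂ upward by ≈ θ²/12 ≈ 0.3%, the dominant term in the
~0.2% net round-trip error; that is far inside the two-significant-figure
resolution the protocol reports.

Peak handling: extrema are located by sign changes of the discrete
derivative (zero-slope runs forward-filled; ties resolved to the earlier
sample) and refined by a quadratic through the three straddling samples —
at 60 Hz and a ~4 Hz pendulum, raw samples alias peak heights by up to
~1%. Extrema below 1° (default `min_amplitude`) are discarded because the
linear law only holds while motion is clearly above the stick regime;
alternating signs are enforced by keeping the larger of two consecutive
same-sign extrema. A fit needs ≥ 4 peaks. A zero-variance envelope
returns slope 0 with R² defined as 1 and a `no-decay` flag; a growing
envelope raises an error. Three trials per joint are averaged
arithmetically, as in the protocol.

## Marker tracking

Motion is rendered as 8 labelled planar markers (mm): 4 rigid to the arm,
4 to the base, with isotropic i.i.d. Gaussian noise (default 0.05 mm; no
published tracking-noise figure exists, so this is a plausible optical
capture residual). Recovery per frame: (i) 2-D Kabsch registration of the
base markers onto their references removes rigid apparatus drift; (ii)
the arm rotation about the pivot is the closed-form orthogonal-Procrustes
angle `atan2(Σ p×q, Σ p·q)`; the series is then phase-unwrapped. With ≥ 3
surviving arm and base markers a frame is solved on the subset; below
that the frame's angle is linearly interpolated (error if > 5% of frames
drop). Arm markers collinear through the pivot are rejected as
ill-conditioned. For equal-radius layouts the first-order angle error is
`σ_marker / (R √n)`, which Monte-Carlo tests confirm within the extra
contribution of base-registration noise.

## Study generator

The generator encodes the study conditions, not free dials:

* Design: 3 genotypes × 12 animals, paired experimental/control limbs;
  16 experimental time points (baseline; 6 through the 2-h loading block
  at 20-min spacing; 1 after the 12-h unloaded rest; 8 through the 24-h
  block at 3-h spacing) and 2 control points (0 h and 38 h wall-clock);
  3 trials per measurement. The within-block sampling times are a package
  choice — the protocol fixes only the block structure and the totals.
* True CoF trajectories are functions of *cumulative loading hours* only
  (observed: no change while unloaded): flat at the genotype baseline
  until a genotype-specific onset, then a linear ramp to the 26-h mean.
  Anchors are the published group values — baselines 0.036 ± 0.0096
  (+/+), 0.030 ± 0.0044 (+/−), 0.077 ± 0.0095 (−/−); finals 0.061 ± 0.034,
  0.12 ± 0.049, 0.13 ± 0.014. Onsets: 0 h (−/−, rise from the start),
  5 h (+/−, midpoint of "flat through 4 h, mild rise by 6 h") and 7 h
  (+/+, flat through 6 h). Intermediate figure-read values are
  deliberately not targeted.
* Noise is multiplicative log-normal, consistent with the log-scale
  analysis: a unit-mean animal effect shared by both limbs of a pair
  (CV set to the baseline SD/mean ratio per genotype) and a unit-mean
  trial effect (default CV 10% of baseline). Unit-mean parameterisation
  keeps group means calibrated by construction. Limitation: a
  time-constant animal effect cannot also reproduce the larger final-time
  SDs (e.g. 0.034 at the wild-type final); the generator matches means
  everywhere and SDs at baseline.
* Histology: per joint, plateau and category, a latent Gaussian at the
  published cell mean/SD, clipped to the category range (structure 0–4,
  surface 0–3, Safranin O loss 0–4) and rounded to the consensus 0.5 grid
  (half-even ties). The five observers and group adjustment are collapsed
  into one consensus score; scores are drawn independently of the CoF
  chain given genotype and treatment.
* `physics` fidelity replaces the trial draw with a full
  simulate→render→track→estimate round trip at the animal-level μ and a
  U[10°, 14°] release.

Passing tests on this generator demonstrate self-consistency of the
measurement chain and correctness of the statistical machinery under the
stated noise model; they cannot validate the biology, the wear mechanism,
or tracking artefacts (soft-tissue movement, marker occlusion) absent
from the model.

## Statistics

Response: natural log of the 3-trial mean CoF; Gaussian mixed model with
a random intercept per animal. Because control limbs are measured only at
the two wall-clock times shared with the experimental schedule, a free
limb × time interaction is unidentifiable; fixed effects are therefore
parameterised cell-means style as genotype × measurement condition
(limb@time), which saturates every observed genotype × limb × time cell
and contains the identifiable parts of the limb, time and interaction
effects. Reported tests are Wald chi-square tests of marginal-mean
contrasts — genotype (averaged over conditions), time (within the
experimental limb), limb (at the shared times) — plus the genotype ×
condition interaction. Pairwise genotype contrasts at baseline and final
time use a t reference with `df = animals − genotypes`, the between-animal
degrees of freedom appropriate for between-genotype contrasts (the
asymptotic normal is slightly liberal at 12 animals/group); contrasts are
unadjusted at the a-priori α = 0.05, with adjustment left to the caller.
A fit whose animal variance is numerically zero proceeds with a
`singular` flag.

Histology: plateau scores are averaged per category and summed to a 0–11
total per joint; each response gets a classical two-way ANOVA
(genotype × treatment with interaction, type-II tables — identical to
type I/III on this balanced design). The CoF–histology association uses
Spearman rank correlation (scores are ordinal), overall and within
genotype; constant inputs are flagged rather than propagating NaNs.

Monte-Carlo problem sizes (package choices): the type-I suite runs 500
replicate studies at the default 12 animals/genotype with a reduced
4-point experimental schedule (baseline, 2 h, post-rest, final), which
preserves the paired structure while keeping each fit small; power,
recovery, calibration and correlation suites use 40–200 replicates at the
same or full schedules.

## Numerical choices and degenerate inputs

* Integrator tolerances rtol 1e−10 / atol 1e−12; energy monotonicity is
  asserted to 1e−8 relative (accumulated integrator error, not physics).
* Trial duration is auto-sized from the predicted decay rate (decay from
  the release angle to `min_amplitude` plus margin, clipped to
  [2 s, 120 s]).
* Release at equilibrium, or anywhere the stick condition already holds,
  stops at t = 0 and downstream peak detection reports insufficient
  oscillation. A duration under one half-period flags a warning.
* All delimited output uses shortest-repr floats, so write→read round
  trips are exact; parsers name the offending line on malformed input.
* Seeds: every stochastic component takes an explicit seed; identical
  seeds give byte-identical study files.

## Known limitations

* Planar (2-D) kinematics; the published capture may have been 3-D.
* The exact geometric constant of the original decay-model code is not
  recoverable; self-consistency between simulator and estimator is the
  contract, not literature-exact constants.
* Linear-ramp wear with a sharp onset is the simplest trajectory matching
  the printed anchors; real wear dynamics are surely smoother.
* Final-time between-animal SDs are under-dispersed (see above).
* No mechanistic lubricin-depletion model, no viability simulation, no
  active-pendulum mechanics — loading enters only through its effect on
  the CoF trajectory.
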