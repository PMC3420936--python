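# Methods

## Calibration of the sensor response

The assay's response curve maps diffusible supercoil density σ_D (≤ 0,
dimensionless) to resolution efficiency R ∈ [0, 1]. Three anchors are fixed
by the assay: R = 0 on relaxed DNA (σ_D ≥ −0.004), R = 0.5 at
σ_D = −0.030, and saturation (R → 1) by σ_D ≤ −0.040. The survey tables
add 31 point-valued (R, σ_D) observations.

**Functional form.** The default is a generalized logistic (Richards)

    R(σ) = (1 + exp((σ − σ₀)/w))^(−ν),  ν = 0.5,

hard-clamped to 0 for σ ≥ −0.004, with (σ₀, w) fitted by weighted least
squares in efficiency space; anchors carry 5× the weight of observations
because they are stated exactly while table pairs are rounded. The
asymmetry is not optional: the printed mappings approach saturation (92% ↔
−0.041) far more steeply than they leave the detection limit (7% ↔
−0.012), and a symmetric logistic that honours the 50% anchor provably
cannot invert 0.92 to within ±0.003 of −0.041 while matching the
low-efficiency spacing. ν = 0.5 is fixed rather than fitted: left free,
least squares over-sharpens the saturating end (the three saturation-side
points dominate) and distorts the low-efficiency limb that most inversions
use. A shape-preserving monotone cubic (PCHIP) through
pooled-adjacent-violator-monotonized points is available with
`method="pchip"` for users who prefer an assumption-free interpolant; it
has no analytic inverse and extrapolates poorly, so it is not the default.

**Inversion.** The Richards form inverts in closed form, so
round-tripping R ∈ [0.05, 0.90] is exact to machine precision.
Efficiencies below the 1% detection limit return a magnitude upper bound
|σ_D| ≤ 0.003 (the bound the tables print for such rows); efficiencies
≥ 95% are inverted but capped at −0.045 and flagged saturated, because the
flat top of the curve carries no more information. Inversions between the
detection limit and the clamp edge return the clamp edge −0.004. Agreement
with printed table values is judged at ±0.003 supercoil-density units —
the tables are rounded to 3 decimals and are internally inconsistent at
that level (the same efficiency maps to σ_D values differing by 0.002
between tables).

**Known outlier.** The Ter-proximal sensor (45% resolution mapped to
−0.022) violates monotonicity against its neighbours; its Res site sits
470 bp from *dif* where region-specific proteins occlude resolvase
binding. The fit warns about it and absorbs it as residual; it is excluded
from genome-wide aggregates (below).

## Resolution statistics

Efficiency per measurement is the unweighted mean of per-replicate
white/total fractions with the sample SD (n−1), matching the triplicate
assay design; binomial pooling is deliberately not used because
between-day variation exceeds counting error. Values under 1% are censored
and enter all aggregates at the 0.5% substitution. MIF is the wild-type
efficiency over the mutant's; a censored mutant yields a lower bound
computed against the 1% detection limit, reported unrounded (the printed
bound cells round inconsistently and are not reproduced). Aggregate MIF is
the ratio of mean efficiencies (not the mean of per-site ratios), which is
how the genome-wide figures of merit are constructed; per-site MIFs are
also emitted in survey reports. Genome-wide aggregates cover the 7
positions outside the Ter macrodomain; the pair flanking rrnG measures the
twin-domain differential, not the genome background, so both exclusions
are explicit, overridable parameters. When a table row carries a printed
apparent σ_D it is used directly for the aggregate's σ mean; otherwise the
efficiency is inverted through the calibration curve. Display rounding
(integer percent, 3-decimal σ_D, 2-significant-figure MIF) happens only at
the report layer.

## Elongation kinetics

Miller units follow the standard formula
1000·(OD420 − 1.75·OD550)/(t·V·OD600); negative values (scatter exceeding
chromophore) clamp to zero with a warning. "Start of the linear increase"
is operationalized as the breakpoint of a continuous two-segment model
MU(t) = b + s·max(0, t − t_b), fitted by exhaustive search over
breakpoints at the 10-s sample grid (closed-form linear least squares per
candidate) followed by golden-section refinement between the two best grid
points — necessary because the lags of interest (44–96 s) span only a few
sampling intervals. The lag is t_b minus the induction time; the rate is
3072 nt (the lacZ transcript) divided by the lag; the twist flux divides
by the B-DNA helical repeat of 10.5 bp/turn, consistent with 45–60 nt/s ↔
4–6 sc/s. The intercept b is fitted, but the reported baseline is the mean
of the ≥3 pre-induction samples only, so post-induction signal can never
shift it. The breakpoint is invariant to rescaling all Miller units. A
square-root linearization (straight line through √(MU − baseline),
x-intercept = lag) is available with `method="sqrt"`; it is exact when
early product accumulation is quadratic, the classic induction-kinetics
shape, and is kept behind a flag because the hinge is the better match to
a piecewise-linear rise. Replicates are estimated independently and
averaged (mean ± SD over colonies).

## Twin-domain simulator

State: σ_i on a ring of n = 450 domains of 10 kb (Lk₀ ≈ 952 turns per
domain). Per time step, each active transcription unit injects −a·v/h
turns/s into its upstream-adjacent domain and +a·v/h downstream (a =
activity, v = elongation rate, h = 10.5 bp/turn); on the closed circle
these fluxes cancel exactly, so with topoisomerases off the total linking
difference is conserved to machine precision. Enzymes act per domain with
linear-saturating laws:

* gyrase: −k_g·clip((σ − σ_set)/|σ_set|, 0, 1), σ_set = −0.038;
* Topo I: +k₁·clip((σ_th − σ)/|σ_set|, 0, 1), σ_th = −0.045;
* Topo IV: −k₄·clip(σ/|σ_set|, 0, 1) only where σ > 0.

Diffusion exchanges σ between neighbours at rate D, gated to zero across
the domain spanned by an active barrier unit. Integration is forward Euler
(dt ≤ 0.01 s at default rates; |σ| > 0.5 aborts); steady state is declared
at max |dσ/dt| < 10⁻⁶ s⁻¹ within 2000–4000 s. These rate laws are the
minimal forms consistent with the measured catalytic speeds — they are
model assumptions, not measured mechanisms. For an isolated downstream
domain with positive-supercoil influx Φ = v/h ≤ k_g the fixed point is
σ* = σ_set·(1 − Φ/k_g), the flux-balance closed form the simulator is
tested against.

**Parameter choices.** k_g = 4.5 sc/s (the measured 4–5 sc/s processive
rate, midpoint), k₁ = 4.5 sc/s (Topo I removes negative supercoils at a
comparable rate), σ_set calibrated to the wild-type survey mean. The
remaining parameters are unmeasured and were chosen once, on mechanistic
grounds: **D = 0.1 s⁻¹** and **k₄ = 0.5 sc/s**. Both matter for the
mutant regime. If inter-domain diffusion is fast (≳2 s⁻¹), the twin-domain
(+) and (−) fluxes annihilate by mixing before either dedicated enzyme
turns over, and a slow-gyrase chromosome never relaxes; if Topo IV is
strong at low diffusion, it destroys the downstream (+) flux before it can
cancel stored (−) supercoils, with the same effect. Slow diffusion with
weak Topo IV lets Topo I continuously drain hypernegative upstream DNA
while weak gyrase fails to replenish the downstream losses — the observed
genome-wide relaxation. Transcription units: 45 evenly spaced,
co-oriented with replication, v = 52.5 nt/s (wild-type genome mean),
activity 0.9, barriers on; unit count sits in the stated 30–50 range of
highly transcribed genes and activity is a free parameter. Presets scale
k_g ×0.5 (gyrA209), ×0.1 (gyrB652/gyrB1820, low-k_cat alleles), k₄ ×0.5
(parE206), v ×0.6 (rpoC Δ215–220); rifampicin zeroes all activities and
dissolves barriers. With these defaults the wild-type steady mean is
−0.041, the gyrB-like mean −0.009, and the post-Rif rebound returns to
σ_set within 10⁻³ — the three regimes the sensors report. Ter-region
anomalies (MatP/FtsK/XerCD occlusion near *dif*) are explicitly not
modelled; simulator output at Cs 33 is not compared to measurements.
Positive σ domains are read as efficiency 0 when mapped through the
calibration curve (relaxed or overwound DNA drives no synapsis).

## Synthetic data

Colony counts: white ~ Binomial(n, R(σ_true)) per replicate, n = 600
colonies × 3 replicates (comfortably above the ≥200 protocol floor),
seeded. Induction traces: MU(t) = baseline + slope·max(0, t − t₀ − lag)·
(1 + ε), ε ~ N(0, 0.05), 10-s sampling with three background samples
before induction, baseline 20 MU and slope 1.5 MU/s — noise magnitudes
chosen to reproduce the printed SD scales (±1–13 efficiency points,
±1–10 nt/s). Traces are emitted as OD-level columns with fixed OD600,
reaction time and volume chosen so the Miller formula reproduces the
target trace exactly. The generators emulate counting statistics and
multiplicative assay noise only: no plate-to-plate growth variation, no
resolvase-expression differences between strains, no position-dependent
activity structure. Passing recovery tests therefore demonstrates
estimator correctness under the assumed noise models, not robustness to
every systematic error of the wet assay.

## Verification scales

Property suites run at the study's scale where that is cheap (450-domain
chromosome, 10⁴-step conservation checks) and at reduced scale where many
repetitions are needed: lag recovery uses 10–20 seeded traces per
condition and σ_D recovery 50 seeded triplicates per true value. The
genome-wide wet-lab measurements themselves are inputs (transcribed
tables), not recomputable quantities; the simulator's qualitative regime
bands substitute for them.

## Limitations

The calibration is only as consistent as the rounded printed pairs
(±0.003); the simulator is a mean-field caricature — deterministic,
equal-sized domains, uniform unit strength, no replication forks,
decatenation or R-loops — adequate for regime-level statements, not for
per-position prediction; the hinge model assumes an abrupt transition to
linear accumulation, while real induction curves bend smoothly over one or
two samples; and the elongation assay measures coupled
transcription/translation, so "elongation rate" inherits any
translation-limited delay.
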