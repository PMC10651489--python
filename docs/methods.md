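# Methods

## Model

The behavioural state is a point `x ∈ ℝ²` in a "need subspace", diffusing
on the potential

    U(x, t) = −log( s·T(t)·φ_w(x) + s·H(t)·φ_f(x) + φ_o(x) )

with `φ_i(x) = N(x; μ_i, σ²I)` ordinary (positive) Gaussian densities.
Defaults place the centres at μ_o = (−8, 0), μ_w = (5, 7.5), μ_f = (5, −7.5)
(near-equilateral; pairwise distances agree to 0.06%) with σ² = 20.  The
log-of-mixture form makes each well locally harmonic with smooth saddles,
and raising a need deepens its well by ~log of the weight.  A sign
convention had to be fixed: we take U = −log(mixture of positive pdfs), the
unique choice under which wells are minima, barriers are positive, and need
increases deepen the matching well.

Dynamics are explicit Euler–Maruyama, exactly the discretization

    x(t+dt) = x(t) + dt·g·(−∇U(x, t)) + √dt·n·ξ,   ξ ~ N(0, I)

with dt = 0.01 s; no higher-order SDE scheme is used because the discrete
update itself is the model.  The gradient is evaluated in closed form.

Choice emission: at each Go-cue time the zone of `x` is emitted, where the
zones partition the plane by the largest *unscaled* density (ties:
miss-first, then water).  With shared isotropic σ² this equals a
nearest-centre rule.  Emissions are therefore need-independent given
position.  A water/food choice enqueues a decrement of T/H by r_w = 0.006 /
r_f = 0.004, delivered after a feedback delay of l = 180 s (the source
material states the delay both as "2 min" and as "l = 180"; the package
default is 180 s and the value is configurable), implemented as a FIFO
queue of due events.  Needs are clamped at 0 from below.  Sessions
optionally terminate after 40 consecutive missed Go cues (configurable or
off), which in practice trims the post-satiation tail.

## Transition theory

Construing the motion along the line between the reward-well centres as a
1-D Smoluchowski process, the escape rate from a reward well over the
intervening ridge is the harmonic transition-state estimate

    ω = √(ν_A·ν_‡)/(2π·γ) · exp(−(E_‡ − E_src)/kT)

with γ = 1, well frequency ν_A = 1/σ², transition-state frequency
ν_‡ = 2/σ² (kept as fixed constants rather than recomputed curvatures),
and energies E = g·U evaluated at the extrema of U on the segment between
the well centres.  Extrema are located by a dense-grid bracket plus
vectorized Newton refinement (tolerance 1e-8); if no interior maximum
exists between the two minima the case is flagged degenerate and the grid
values are used.  A two-state master equation with these rates gives the
closed-form self-transition probability

    P_ww(t) = (1 − π_w)·e^{−(ω_wf+ω_fw)t} + π_w,   π_w = ω_fw/(ω_wf+ω_fw)

and the row-stochastic transition matrix P(t).

**Thermal identification.**  The Fokker–Planck equation of the update above
has stationary density ∝ exp(−2·g·U/n²), i.e. kT = n²/2 (the commonly
quoted shortcut n ≈ √kT drops the factor 2 of the Einstein relation).  The
package uses kT = n²/2 in every theory expression.  This was verified
empirically: long fixed-need simulations at the default fitted parameters
occupy the water/food/other zones at 0.500/0.343/0.157, against Boltzmann
predictions of 0.474/0.350/0.177 with kT = n²/2 but 0.399/0.342/0.259 with
kT = n².  The same identification makes parameter fitting on simulated
data consistent.

**Boltzmann choice probabilities.**  Zone-wise midpoint quadrature of
exp(−g·U/kT) over [−25, 20]×[−20, 20] (≥5σ past every centre) at spacing
0.125, normalized over the two reward zones (per-choice probabilities) or
all three zones (satiation analyses, misses included).  A self-check
recomputes at half the spacing; at the default spacing halving moves
probabilities by <1e-4.  When a need is exactly 0 its zone integral is
still computed — the mixture's other components leak density into the
zone, so the zero-need limit of P(other) is 0.85, not 1 (the exponent
g/kT ≈ 0.65 < 1 flattens the single-well density well past its zone
boundary).

## Fitting

Three datasets are built from annotated trial tables: (i) sequential
rewarded pairs with no intervening miss, tagged with the needs at the
previous reward and the elapsed time; (ii) rewarded trials with neither
flanking Go trial a miss; (iii) Go trials, misses included, with thirst
**and** hunger < 0.5 (conjunction — the intended "near satiation" reading).
The loss is the sum of the three per-trial mean negative log-likelihoods:
pairs under P(t), choices under the two-zone Boltzmann probability, and
satiation trials under the three-zone probability.

Gradients with respect to (g, n, s) are closed-form: the Boltzmann terms
differentiate into Boltzmann-weighted zone means of U and of s·∂U/∂s
(∂U/∂s = −(1 − φ_o/M)/s), and the barrier terms use the envelope theorem
at the located extrema, so no autodifferentiation library is needed; the
analytic gradient matches central finite differences to ~1e-9 relative.
Positivity is enforced by optimizing (log g, log n, log s).  The default
optimizer is Adam at learning rate 0.1 with the Boltzmann terms
mini-batched (fraction 1/50, floor 256 trials, re-drawn per epoch) and
convergence declared when the smoothed loss stalls below 1e-6 for 50
epochs; a full-batch L-BFGS path with the same gradient is available and
is what the recovery tests use.  Fitting uses quadrature spacing 0.25 by
default (a 4× cheaper grid whose probabilities differ from the reporting
grid by ≪ the statistical error of any batch).

Reference parameter presets are shipped as constants: the full-dataset fit
(g = 2.4383774, n = 2.74393, s = 6.4874935) and the recording-subset fit
(g = 2.5563507, n = 2.807799, s = 6.4874935).  They are inputs, not
reproduced quantities.

## Behavioural statistics

Behavioural thirst (hunger) at a trial = rewards of that type still to be
collected in the session, normalized by the dataset-median session total;
relative need = (T−H)/(T+H), undefined (NaN, excluded) when both are 0.
Note the annotation counts the current and future choices themselves, so
it is mechanically coupled to outcomes: even need-blind coin-flip choices
regress on relative need with slope ≈ 0.38.  Null tests therefore permute
the need column rather than assuming a flat slope.

Bouts are runs of identical consecutive rewarded choices (misses and No-Go
cues do not break a run); the geometric MLE is 1/mean(run length) and CIs
bootstrap over sessions (1,000 resamples by default — session-level
resampling throughout, the conservative level for session-clustered data).
Binned estimates use 5-percentile-wide quantile bins of the pooled
relative-need distribution with stable tie handling.  The self-transition
regressions exclude trials with fewer than 10 remaining rewards of either
type.  The balanced-need transition matrix restricts to |relative need| ≤
0.25.  The upcoming-choice predictor comparison fits RBF-kernel SVMs
(C = 1, variance-scaled kernel width) per session on a random 50% split.
Choice-time densities around stimulation onsets use Gaussian KDE with
Scott's bandwidth.  Goal-dimension analyses project positions onto
(μ_w − μ_f)/‖μ_w − μ_f‖ (the y axis under the default geometry); the
switch-probability rescaling of |goal − midpoint| uses a 1-D linear
discriminant.  Phase portraits take per-trial (position, next-trial
change) on the goal axis, label switch trials, and quantify stay/switch
velocity densities inside a transition zone of half-width 3.75 (half the
projected inter-well distance, configurable), with 1,000 resamples to a
target switch fraction.

## Synthetic data

`session_gen` emulates the assay's cue process: cue onsets separated by a
fixed 1.5-s odour allowance plus i.i.d. uniform [2, 8]-s intervals, Go with
probability 0.67; datasets default to 22 two-hour sessions with initial
needs drawn uniformly from [0.8, 1.2]² (≈ the normalized need of a
restricted subject at session start; with r_w = 0.006 a unit of thirst is
≈167 water rewards).  The generator returns an experiment-format view
(session id, time, label, outcome — nothing else) and a separate
ground-truth view (trajectories, true needs, seeds, generating
parameters).  It emulates cue timing and the need-feedback loop; it does
not emulate lick kinematics, sensory errors, day-to-day variability or any
neural observable, so passing tests say nothing about those aspects of
real data.

## Forced-transition alternative model

The contrast model keeps the landscape but reduces the noise to n = 0.5,
at which no spontaneous switch occurs over a session, and adds
Poisson-timed impulses along the goal axis that displace the state past
the ridge between the reward wells, with no noise on the force.  The
impulse lands 2.0 units beyond the ridge: the ridge-region thermal length
at n = 0.5 is ≈0.7, so a smaller margin would let diffusion re-cross and
violate the one-impulse-one-switch contract; 2.0 is the smallest margin
that makes the descent into the far well effectively deterministic while
remaining "just past the saddle".

## Problem sizes

Default analysis scales, chosen as comfortable desk-scale equivalents of
the study conditions: 22 sessions × 2 h per simulated dataset (the
compiled integrator runs a session in ~0.1 s); 30,000 s fixed-need runs
for equilibrium checks; 150 first-passage replicates per need setting;
bootstrap sizes 50–1,000 depending on context.  The acceptance script
completes in well under a minute after compilation.

## Known limitations

* **The simulator switches faster than its own theory.**  At the default
  fitted parameters the water↔food barrier saturates at g·ΔU ≈ 1.74 for
  all balanced needs while kT = n²/2 ≈ 3.76, so the deep-well premise of
  the Kramers estimate fails: the measured attempt frequency is ~4.5× the
  harmonic prefactor (which also omits the mobility factor g), and the
  realized transition rate ≈0.03 s⁻¹ versus the predicted ≈0.007 s⁻¹.
  Consequences, all verified by the acceptance suite: simulated bouts
  average ~5 choices (geometric p ≈ 0.20) rather than the ~16 the theory
  implies; balanced-need repeat probability is ≈0.84, not >0.9; the
  self-transition slopes are ≈±0.21; first-passage rates sit ~6× above
  the closed-form rates.  The transition-rate theory remains a good
  *shape* model (exponential relaxation toward the correct Boltzmann
  equilibrium) but its rate scale is only order-of-magnitude in this
  shallow-barrier regime.
* **Equilibrium likelihood vs non-equilibrium data.**  Near satiation the
  state lags the shrinking reward wells (hysteresis, amplified by the
  180-s feedback delay and miss-run termination), producing more misses at
  moderate annotated needs than the equilibrium Boltzmann term predicts.
  Fitting simulated data therefore recovers g and n well (within ~±15%)
  but biases s low by ~40–55%.
* The identifiable parameter combination of the likelihood is (g/n², s):
  the Kramers prefactor carries no g or n, so g and n separate only
  through the initialization and the optimizer path.
* Zone emission is instantaneous and noiseless; there is no anticipatory
  need dynamics, no hysteresis in the need update beyond the fixed delay,
  and no within-trial (lick-level) behaviour.
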