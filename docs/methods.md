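# Methods

## The model

`gnrhsync` simulates intracellular calcium dynamics in cultured embryonic
GnRH neurons, at two levels.

**Single cell.** Each cell is a three-dimensional slow–fast system of
FitzHugh–Nagumo type:

```
x'  = τ (−y + 4x − x³ − φ_fall(Ca))
y'  = τ ε k (a₀x + a₁y + a₂ − drive)
Ca' = τ ε (φ_rise(x) − (Ca − Ca_bas)/τ_Ca)
```

with `φ_fall(Ca) = μ Ca/(Ca + Ca₀)` and
`φ_rise(x) = λ/(1 + e^{−ρ_Ca(x − x_on)})`.  `x` is the fast (average)
electrical activity, `y` the recovery variable, `Ca` the calcium
concentration in nM.  `ε` separates the fast and slow time scales; `τ`
rescales model time so that one unit of integration time is one minute of
experimental time.  Activity drives calcium entry through `φ_rise`;
calcium feeds back on excitability through `φ_fall`, whose gain `μ`
selects the attractor:

* small `μ` — relaxation oscillations: periodic calcium peaks with no
  quiescent phase;
* intermediate `μ` — mixed-mode oscillations (MMOs): large peaks separated
  by small sub-threshold oscillations of `x` near the lower fold of the
  cubic nullcline.  The small oscillations are the model's account of the
  quiescent phase between calcium peaks;
* large `μ` — a single transient peak, then a stable rest state.

The transitions are canard explosions; for the default parameter set they
occur at `μ ≈ 2.26` and `μ ≈ 2.45`, located here by bisection on a
simulation-based classifier.  The default (reference) parameter set
produces a 10-minute inter-peak interval (IPI), ~342 nM peaks, a ~100 nM
baseline and a quiescent phase about twice the peak duration — the average
quantitative features reported for calcium imaging of embryonic GnRH
neurons.  `μ` mainly tunes the IPI and `k` the peak height (and period),
which is how inter-cell variability is produced.

**Network.** N cells, heterogeneous in `k_j` (and optionally in coupling
sensitivity `η_j`), are coupled only through one super-slow scalar `σ`:

```
y_j' = τ ε k_j (a₀x_j + a₁y_j + a₂ − η_j φ_syn(σ))
σ'   = τ (δ ε σ − γ (σ − σ₀) φ_σ( mean_i(Ca_i) − Ca_desyn ))
```

with logistic activations `φ_syn` (threshold `σ_on`, slope `ρ_syn`) and
`φ_σ` (threshold 0, slope `ρ_σ`).  While the population is asynchronous
the mean calcium stays low, `φ_σ ≈ 0`, and `σ` grows as
`σ' = τδεσ`.  When `σ` crosses `σ_on` every sufficiently sensitive cell is
driven across its excitation threshold almost simultaneously — a
synchronized calcium surge with higher-than-usual peaks, followed by a
common return to baseline (postexcitatory suppression).  If the surge
pushes the population-mean calcium above `Ca_desyn`, the reset term pulls
`σ` back toward `σ₀` and the cycle restarts.  The inter-episode period in
the strong-reset, steep-`φ_σ` limit is

```
T_syn = ln(σ_on/σ₀) / (τ ε δ),
```

so `δ` can be chosen for any prescribed period (`δ = 0.05` gives ~60 min
with the default constants; the measured trigger-to-trigger interval is
~60–61 min, the excess over the formula being the episode duration).  Only
the ratio `σ_on/σ₀` is identifiable from calcium outputs: the
transformation `(σ₀, σ_on, ρ_syn) → (ασ₀, ασ_on, ρ_syn/α)` maps the system
onto itself with `σ → ασ`, leaving every `Ca_j` unchanged.

## Parameter presets

* `table1` — the reference single cell (`a₀=1, a₁=−0.1, a₂=0.8, k=1,
  ε=0.06, τ=37, μ=2.4, Ca₀=500, Ca_bas=100, τ_Ca=2, λ=175, ρ_Ca=4.5,
  x_on=−0.45`).
* `table2-full-sync` — network constants for full synchronization every
  ~60 min (`δ=0.05, γ=20, η_j=3, Ca_desyn=350, ρ_syn=5, ρ_σ=30, σ_on=60,
  σ₀=0.1`).  `Ca_desyn` sits just above the mean single-cell peak height so
  that only a collective surge can trigger the reset.
* `table3-doublets` — weak coupling and slow reset (`γ=0.3, η_j=1.12,
  Ca_desyn=380`, rest as above), the regime in which synchronization
  episodes can come as doublets.

Heterogeneity defaults are `k_j ~ U[0.8, 1.2]` (giving IPIs from ~4 to
~17 min across cells) and, for partial-recruitment runs,
`η_j ~ U[0, 3]`.

## Numerics

The systems are stiff: `ε = 0.06`, sigmoid slopes up to `ρ_σ = 30` per nM,
and the canard-sensitive small oscillations are destroyed by loose
integration.  Trajectories are integrated with LSODA at `rtol 1e−8` and
per-variable `atol` (`1e−10` for x and y, `1e−6` nM for Ca, `1e−8` for σ),
maximum step 1 min, and resampled on a 0.01-min output grid.  Halving the
tolerances moves peak times by less than 0.01 min.  Upward crossings of
`σ_on` are located by the integrator's event detection, not from the output
grid.  Sigmoid exponents are clamped at ±700 so that Heaviside-limit
parameter sets (slopes up to 1e6) evaluate without overflow.

Equilibria are found by bracketed scalar root finding (Brent) in `x` after
substituting the calcium nullcline and the critical manifold into the
`y`-nullcline; the parameter invariant `a₀/|a₁| > 4` guarantees a unique
root.

The rest point of the reference cell sits ~2·10⁻³ to the *right* of the
lower fold `x = −2/√3`; it drifts left as `μ` grows and crosses the fold
between `μ = 2.45` and `μ = 3`.  The regime classifier therefore does not
use the fold as a strict boundary: a sub-threshold oscillation is a local
maximum of `x` below 0 (well short of a full excursion to the right
branch, whose maxima sit near `x ≈ +2.3`), detected in the final half of a
150-min trace after a 50-min burn-in — a window long enough to hold at
least two peaks even at the slow periods reached near the regime
boundaries.  A large peak is a calcium excursion above baseline + 100 nM;
a steady state is a final-window calcium amplitude under 1 nM.

## Feature extraction

A calcium peak is an excursion above `baseline + 100 nM` (baseline = 5th
percentile of the trace); its `t_max` is the excursion maximum and its
return time is the first decay back to within 1 nM of the baseline (the
decay is asymptotic, so any return level far above baseline would
understate the peak duration; with this definition the reference pattern's
quiescent phase is ~1.8–2.2× the peak duration).  IPI values are
differences of consecutive `t_max`.  The MMO small oscillations are a few
nM in Ca and never cross the detection level.

A synchronization event is one upward crossing of `σ_on`; cells whose peak
maximum falls in `[trigger − 1, trigger + 5]` min participate, and the
episode tightness is the spread between the earliest and latest
participating peak, in seconds (onset-based tightness is available by
flag).  Recruitment is classified per cell against its own median
asynchronous peak height: `full` above 1.10× that reference, `partial` at
or below it, `none` without a peak in the window.  The 1.10 factor is
calibrated so that uniformly strong coupling (`η_j = 3`) classifies every
cell as fully recruited — slow cells have high asynchronous peaks, leaving
synchronized/asynchronous ratios as low as ~1.13 — while heterogeneous
sensitivity (`η_j ~ U[0, 3]`) still separates all three classes.  Events
closer than 15 min share a doublet label (between the printed ~7–8 min
intra-doublet gaps and the ~56–60 min inter-phase period).

## Initial conditions

The generic network start is `σ = 1.01 σ₀` with each cell at the
drive-free rest point, calcium forced to baseline (just below the lower
fold, so each cell launches one excursion), then desynchronized by
integrating each cell alone for a seeded burn-in time `~ U[0, 30]` min.
All randomness derives from a single master seed through SeedSequence
spawn keys, one child per purpose, so adding a pipeline stage never
perturbs earlier draws.

## The doublet regime is a knife edge

With `γ = 0.3` the reset time constant is `1/(τγ) ≈ 0.09` min, so the
intra-doublet gap is set by how long the mean calcium stays above
`Ca_desyn`: a ~7–10 min gap corresponds to a *grazing* crossing of only
~5 s.  Whether an episode grazes depends on the phase coherence of the
population at the trigger: per-cell driven peaks reach ~400–425 nM, and
with fully dispersed phases the population-mean surge tops out at
~345–370 nM — below the 380 nM threshold — while a partially coherent
population reaches ~375–385 nM.  The doublet experiment therefore starts
all cells from a common on-attractor state, probes first-trigger times of
4, 8 and 19 min (three coherence levels), and scans heterogeneity
realizations (in a deterministic seed-derived order) for ones whose
episode grazes the threshold.  Measured intra-doublet gaps are averaged
over the doublets found (typically ~8–11 min).  Episodes triggered from
fully dispersed populations usually fail to cross the threshold at all, in
which case `σ` grows without further resets; as a consequence the full
printed sequence (doublet → ~56 min asynchronous phase → next doublet)
requires two consecutive grazing episodes and is only expressed by
occasional realizations.  The package measures the post-doublet
separations whenever a scanned realization expresses them rather than
asserting them unconditionally.

## What the simulations do and do not show

All inputs are model-generated; there is no real imaging data in the
pipeline.  The synthetic runs reproduce the model's printed behaviour —
IPI and peak statistics, regime boundaries, the ~61-min synchronization
rhythm, recruitment classes, postexcitatory suppression, rescaling
invariance — under the stated presets and heterogeneity laws.  They do not
model photobleaching, spatial structure, measurement noise, or
Hodgkin–Huxley-level membrane dynamics, so passing tests validate the
dynamical mechanism, not a fit to raw experimental recordings.

## Problem sizes used in tests and the acceptance script

Single-cell analyses use 120 min of trace after a 50-min burn-in.
Regime bisection classifies ~17 parameter points to a tolerance of 0.005
in `μ`.  Network runs use N = 50 for 130–180 min; the rescaling-invariance
check integrates N = 50 for 15 min through one episode at `rtol 1e−10`
(with `atol` on σ scaled by α, since σ itself is scaled).  The doublet
scan probes at most 8 realizations × 3 trigger times with ~20–40-min
event-only runs, then runs each doublet-expressing realization (at most
three) for 150 min, keeping the first that also shows a post-doublet
synchronization phase.
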