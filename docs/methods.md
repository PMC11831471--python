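# Methods

## The model

One transducer is a micrometer particle tethered above a sensing surface,
carrying a discrete number `N_PSB` of particle-side binders that compete
between analyte in solution (concentration `[A]`) and `N_SSB` substrate-side
binders. Every intermolecular step is an independent Poisson process, so the
system is a continuous-time Markov chain on states `(a, b)` — `a`
analyte-occupied PSBs, `b` particle–surface bonds — with the constraints
`a + b ≤ N_PSB`, `b ≤ N_SSB`. The particle is *bound* iff `b ≥ 1`; the sensor
signal is the switching activity, i.e. the frequency of `b: 0 ↔ 1` crossings.
Non-specific interactions, steric/geometric effects, tether mechanics, and
the encounter physics behind the effective bond-formation constant are
deliberately outside the model.

Bond formation uses mass action on discrete counts, propensity
`k*_on · f · s` with `f` free PSBs and `s` free SSBs. Whether the effective
`k*_on` should scale with the number of available surface binders is not
settled; the alternative propensity `k*_on · f` (independent of `s` as long
as `s ≥ 1`) is implemented behind the `bond_rate_scales_with_ssb` switch.
Mass action is the default because it is the simplest rule consistent with
independent pairwise Poisson interactions.

Two dissociation constants are carried (`k_off_analyte`, `k_off_bond`) but
equal by default — the competition chemistry uses the same antibody paratope
for analyte and surface analogue, so a single `k_off` is the natural default.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| `k_on` | 1e5 | 1/(M·s) | typical antibody–small-molecule association |
| `k_off` (both) | 0.01 | 1/s | 100-s bond lifetime; with `k_on` gives K_D = 100 nM |
| `k*_on` | 1e-3 | 1/s | sets monovalent blank activity ≈ 6.5 events/h and places the sigmoidal→bell transition at `N_SSB ≈ 4` for `N_PSB = 10` (verified on the exact oracle) |
| `λ_PSB`, `λ_SSB` | 0 (scenario: 2.22e-6 ≙ 0.8 %/h each) | 1/s | together they decay the binder product at 1.6 %/h, the drift scale the protocol it emulates reported |
| Poisson means | 3 (PSB), 8 (SSB) | – | oracle class map gives ≈70 % sigmoidal / 25 % bell / 5 % non-responsive: a sigmoidal-dominated but visibly heterogeneous ensemble |
| ladder | 7 log-spaced points, 1e-2…1e2 × K_D, blank last | M | spans the full competition transition; applied high→low |
| schedule | 10 series × 8 applications; 900 s tracked + 225 s dead | s | 2.5 h per series, 25 h total |
| `bell_ratio` | 0.8 | – | a curve is bell only if the blank end falls below 80 % of an interior maximum |
| `floor_activity` | 2 | events/h | below ≈0.5 events per tracked window a curve carries no shape information |
| phase bins | six `π/6` bins spanning `[−π/3, 2π/3]` | rad | covers the named sigmoidal `(−π/6, 0)` and bell `(π/6, π/3)` bins plus margins |
| amplitude floor | 10 % of ensemble fundamental | – | "non-responsive" phase criterion |
| motion | radii 150/30 nm, step 50 nm/frame, noise 5 nm, 30 Hz | nm | step ≈ `sqrt(2 D Δt)` of a micron bead near a wall; radii give well-separated RMS levels |

Rate constants and ladder are tagged `assumed` in the config provenance map:
they are package-chosen operating points, not published values. Schedule
counts and the loss scale are tagged `protocol`.

## Exact oracle and simulator

For loss-free configs with counts ≤ 12 (configurable) the stationary
distribution is solved directly from the generator (`πQ = 0`, normalized;
residual checked to 1e-10). Switching activity is `2 Σ_a π(a,0)·(bond
formation propensity)`, the single-bound fraction `Σ_a π(a,1)`. The state
space is enumerated `b`-major, `a`-minor, ascending.

The simulator is the direct Gillespie method — two uniforms per event, one
for the exponential waiting time, one for the reaction — with the waiting
time re-drawn at every concentration change (exact by memorylessness).
Binder loss removes a *free or analyte-occupied* PSB (chosen proportionally
to current counts) or a *free* SSB; removing bonded binders would conflate
loss with bond release, but the severing variant exists behind
`loss_severs_bonds`. Traces are reproducible bit-for-bit from
`(config, profile, seed)`; populations use substreams keyed
`particle/<index>` from a master seed, so enlarging a population never
reshuffles existing particles.

Before `t = 0` each trace runs a burn-in of ten mean unbound lifetimes
(`10 / (k*_on N_PSB N_SSB)`) at the initial concentration with loss disabled
and events discarded, approximating particles observed after equilibration;
it is configurable, including off.

## Observables and dose-response analysis

Activities are computed on exact event traces; finite-frame-rate sampling
(`frame_sample`) is opt-in, so simulator-level results are sampling-free.
Lifetime means exclude window-edge (censored) intervals. Per-particle DRCs
are the activities of the 8 tracked windows of one series; the time-averaged
DRC is the mean over the 10 series with per-point SD.

Shape classification: non-responsive if the maximum activity is below the
floor; bell if the maximum sits at an interior concentration (neither the top
concentration nor the blank) *and* the blank-end activity is below
`bell_ratio` × maximum; otherwise sigmoidal. EC50 comes from a
four-parameter logistic in log concentration, with the blank anchoring the
low-concentration asymptote; fits outside the ladder are flagged
extrapolated. For a strictly monovalent particle the model DRC is exactly
logistic with Hill slope 1 and
`EC50 = K_D (1 + k*_on N_SSB / k_off)` — competition with the surface shifts
the midpoint above the solution K_D, and more surface binders shift it
further right, up to the bell transition.

## Phase-shift classification

Per series, each particle's 8-point activity signal is mean-subtracted and
its discrete Fourier coefficient at one cycle per series is compared with the
ensemble mean signal's: `Δφ = arg(particle) − arg(ensemble)`, wrapped to
`(−π, π]`. With the ladder applied high→low, bell-shaped particles peak
earlier in the series, which makes their signal *lead* the ensemble and gives
`Δφ > 0`; an 8-point cosine advanced by one sample gives exactly `+π/4`.
Bins are left-open/right-closed, so a value exactly on an inner edge belongs
to the lower bin. Bin membership is frozen from the first series;
bin-resolved mean DRCs and per-bin trajectories of mean phase and amplitude
then track migration over the 25 h.

One caution: per-particle *single-series* shape labels are meaningless at
realistic event rates (a handful of events per 15-min window), which is the
very reason the phase shift exists as a classifier. Migration statements
about DRC shape are therefore made on the *bin-averaged* DRCs, where
averaging over ≥ tens of particles restores the shape; `track_migration`
still reports the per-particle modal labels for completeness.

## Binder-loss estimation

The loss estimator is the ordinary-least-squares line through the ensemble
blank-window activities versus time, reported as `−slope/intercept × 100`
%/h with a delta-method SE from the full fit covariance. It requires ≥ 3
blank windows spanning > 2 h and flags a non-positive intercept. The
estimator is exact for linear decay by construction. For first-order loss
the true decay is exponential, and on a 25-h horizon with 1.6 %/h the
linearization makes the estimator read low: applying the same OLS to the
exact exponential gives ≈ 1.31 %/h, and the small bond-occupancy saturation
of the activity lowers the expectation further (≈ 1.18 %/h at the default
rates; the loss-recovery test computes the realized value). The estimator is
kept in its linear form deliberately — it is the measurement the emulated
protocol defines — and it is only meaningful in the monovalent regime:
multivalent particles *gain* activity as they lose binders.

## Motion layer

The video pipeline stand-in synthesizes positions as a Gaussian random walk
radially reflected at the state-dependent confinement radius (stationary law:
uniform on the disc, so the unbound RMS radial distance is `R/√2`), plus
localization noise. Detection thresholds the centered rolling-window RMS
radial excursion about the anchor with hysteresis (enter/leave at
`threshold × (1 ∓ hysteresis)`), requires a crossing to persist for a full
window, localizes the change point at the mid-threshold crossing (backtracked
at most one window), and merges detected dwells shorter than two windows.
A centroid-relative RMS was rejected: at video rates a 0.5-s window does not
explore the confinement disc, so only the anchor-relative excursion separates
the states. This layer is a functional stand-in for image-based tracking,
not a reimplementation of any particular tracking algorithm.

## What the synthetic data does and does not emulate

The generator reproduces the protocol structure (ladder, series, tracking
windows), Poisson binder-number heterogeneity, and first-order binder loss.
It does not emulate non-specific sticking, diffusion-limited transport or
rebinding, fluid-exchange transients, inter-particle competition for analyte,
localization drift, or particle misidentification. Tests passing here
validate the kinetic model, the estimators and their statistical behavior —
not the imaging chain or surface chemistry of any real instrument.

## Numerical choices and limitations

* CTMC solves are dense and capped at 12×12 binder counts by default; beyond
  that, only the simulator path is supported.
* Event traces can be recorded in full or restricted to bond/count events
  (`record="bonds"`); all state observables are exact either way.
* Monte Carlo test tolerances are 3 standard errors from batch means
  (10 batches), with fixed seeds throughout; every random draw in the package
  flows from an explicit seed (a test enforces that the global numpy RNG is
  never touched).
* Problem sizes in the validation suite — 200-h oracle-comparison runs,
  400-h product-law runs, 500-particle 25-h population experiments — were
  chosen to keep Monte Carlo error a few percent of the quantities under
  test; at these sizes the full suite runs in well under a minute of compute
  per heavy test.
* Degenerate transducers (`N_PSB = 0`, `N_SSB = 0`, or `k*_on = 0`) are
  legal and permanently unbound, not errors.
* `EC50` fits on bell-shaped or non-responsive curves are refused rather than
  returning numbers without meaning.
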