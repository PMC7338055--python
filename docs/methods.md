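# Methods

## Model

A microtubule (MT) nucleating from γ-TuRC is represented as 13
protofilament stacks of αβ-tubulin dimers on a ring of 13 permanent
γ-tubulin sites. Stacks are contiguous by construction: dimers add only on
top, and a dissociating dimer takes everything above it in its
protofilament along. Dimer-resolution only (no α/β distinction), no GTP
hydrolysis, no catastrophe/rescue, no lattice mechanics, and the free
tubulin concentration is held constant.

Energies are in kBT (kBT ≡ 1), negative favourable. A dimer's total bond
energy is its single longitudinal bond (γ–αβ for layer 1, αβ–αβ above)
plus `w·ΔG_lat`, where `w` is its lateral contact weight. Detailed balance
per site sets the off-rate, `k_off = k_on · exp(ΔG_tot)`, with the 1 M
standard state absorbed into the convention (as in classic stochastic
plus-end models).

**Seam.** The B-lattice pitch of 3 monomers (1.5 dimers) is implemented as
a half-dimer effective offset: a dimer at layer *i* on the last
protofilament half-overlaps layers *i* and *i+1* on protofilament 0, each
contact counting 0.5. Whole-dimer parts of the offset are relabelings of
the layer index and are dropped; the direction of the shift is arbitrary
and fixed once. A complete first layer therefore carries 12.5 lateral
weight (12 full bonds + one seam half).

**Conformational switch.** Native γ-TuRC is *open*: no lateral αβ–αβ bonds
form, at any layer. It closes irreversibly at rate
`k_conf · exp(−ΔG_close)`, `ΔG_close = ΔG_conf − n·|ΔG_lat|`, where *n* is
the total prospective lateral weight of the resident dimers. The magnitude
`|ΔG_lat|` is used so that prospective bonds *lower* the barrier — the
literal signed form would have favourable lateral energies raising it,
contradicting the mechanism; the signed variant is kept behind
`EnergyParams(closure_sign="literal")` for sensitivity checks. The closure
rate is the pure Arrhenius form with no cap, even when `ΔG_close < 0`.
Closure time = nucleation time; the heights vector at that instant is the
transition-state snapshot.

**Seed (blunt-template) mode** starts from an empty *closed* template with
the γ-bond set equal to the αβ–αβ bond, and records nucleation when the MT
first reaches 50 nm, using the mean-height length reduction
`length = mean(heights) · 8 nm`. The tallest-protofilament reduction is
available (`seed_length_reduction="tallest"`) since single-trajectory
traces are often plotted that way; the two differ only modestly here.

**Dissociation channels.** By default only the terminal (topmost) dimer of
each protofilament carries a dissociation channel. The alternative of
giving every occupied dimer a channel (executing one removes everything
above it) is available as `dissociation="all"`, but with per-dimer rates
based on each dimer's own bonds it produces avalanche catastrophes —
an interior cut strips a column, halving its neighbours' lateral support
and raising their off-rates by e^6.5 — capping MTs at a few hundred dimers
with ~0.4 nm/s net growth at every concentration. That regime is
irreconcilable with the micrometre-scale growth and the near-linear
growth-speed curve the energy parameters are calibrated against, so it is
a sensitivity switch, not the default.

## Stochastic drivers

The reference driver is the first-reaction method: one exponential waiting
time `t_i = −ln(R_i)/k_i` per event, execute the minimum. The production
driver is a numba-compiled direct (total-propensity) kernel — draw
`Δt ~ Exp(ΣK)`, pick a channel with probability `k_i/ΣK` — which is
distributionally identical; the equivalence is covered by tests (analytic
selection frequencies and waiting-time law, plus a two-sample KS between
the drivers' nucleation-time distributions). All rates are recomputed from
the state after every event; the kernel's two walks (summation, selection)
iterate channels in the same order. Per-trajectory seeds derive from the
master seed by `numpy` SeedSequence stream splitting, folded into the
positive int32 range; fixed seeds reproduce trajectories bit-for-bit.

## Estimation pipeline

Ensembles per concentration give `p(t)` = fraction of all trajectories
nucleated by `t` (censored runs stay in the denominator). The initial rate
is the OLS slope of the earliest part of the curve; "initial" is quantified
as the window up to where the curve first exceeds 20% of its final value,
with at least 5 grid points — the window rule is configurable and reported
with every fit. The default grid spacing for simulation-derived curves is
0.25 s, fine enough to resolve the fastest median nucleation times (~1 s at
the top of the concentration sweep). Exponents come from unweighted OLS in
log-log space; uncertainty is the OLS slope standard error (a bootstrap
over MTs is the natural alternative and can be layered on the event
tables). Zero-rate concentrations cannot enter a log fit and are excluded
and reported; in the simulation pipeline, rate points backed by fewer than
10 nucleation events can additionally be excluded (`min_events`), since a
handful of events gives a Poisson-noise-dominated slope. Seeded assembly is
fitted against `ln(C − C*)`; with `C* = 0` this reduces exactly to the
plain fit. Normalising all rates to the 10.5 μM point (or any reference)
leaves exponents invariant and allows pooling replicates with different
nucleator counts. Poisson bands on counts are `N ± 2√N`, clipped at zero.

## Synthetic data generator

`gturcsim.synth` draws the data the estimators assume: exponential
per-nucleator waiting times with rate `k·C^n` (template), Poisson counts
with mean `k·C^n·τ` (spontaneous), exponential waits with rate
`k·C^(n−1)·(C−C*)` (seeded), and speeds `a·(C−C*)` plus Gaussian noise
(growth). Administrative censoring at the movie length only; an optional
additive detection delay (default 0) stands in for the back-extrapolation
used on real movies. Concentrations are in μM and `k` absorbs units, so
exponents — not rate constants — are the comparable quantities. What the
generator deliberately omits: field-of-view heterogeneity beyond Poisson
counting, photobleaching, localisation error, growth-speed dispersion, and
nucleator depletion. Passing recovery tests therefore show estimator
correctness under the model's own assumptions, not robustness to every
artefact of real imaging data.

## Default problem sizes

Headline computations use 120–200 trajectories per concentration
(500/400 at the two lowest XMAP215-preset concentrations, where initial
rates rest on tens of events and Poisson noise dominates the log-log fit),
t_max = 500 s, and stop-at-nucleation; the census pools the 7–28 μM series
(~700 snapshots). These sizes put seed-to-seed scatter of the exponents
near ±0.1–0.2 while keeping a full reproduction run at a few minutes on
one CPU.

## Known limitations

- Near the polymerization threshold the model's growth speed is convex in
  concentration (local log-log slope ≈ 2 over 2.45–7 μM) rather than the
  linear `a·(C − C*)` seen experimentally. Seed-mode "time to 50 nm" rates
  inherit that superlinearity, so the seeded exponent lands at ~1.3–1.5
  instead of ~1.1: new-layer initiation on a blunt closed template adds a
  cooperative lag that the printed parameter set does not linearise. The
  template-mode exponent, the transition-state census and the XMAP215
  contrast are insensitive to this.
- The OLS slope standard error of a log-log fit with few concentrations
  under-covers: with 5 points a 2-SE interval cannot exceed ~86% coverage
  even when perfectly calibrated (t with 3 dof). Calibration tests use 8
  concentrations per design.
- The all-dimer dissociation switch exists for sensitivity analysis but,
  as noted above, is not a physically meaningful growth regime under the
  per-dimer rate rule.
- Open-state occupancies are low at the concentrations of interest, so
  nucleation at the lowest concentrations is event-starved; rates there
  are reported but excluded from fits by the `min_events` floor.
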