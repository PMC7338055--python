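# gturcsim

Kinetic Monte Carlo model of microtubule (MT) nucleation from the
γ-tubulin ring complex (γ-TuRC), together with the statistical pipeline
that turns nucleation kinetics into an estimate of the critical nucleus —
the number of αβ-tubulin dimers in the rate-limiting transition state.

## Who this is for

Quantitative cell biologists and biophysicists studying MT nucleation:
anyone who wants to (a) simulate templated MT nucleation with explicit
tubulin bond energetics and a conformational switch, (b) analyse
single-molecule TIRF nucleation time courses (real or simulated) with
power-law critical-nucleus estimators, or (c) stress-test those estimators
on synthetic data with known ground truth.

## The model

The MT wall is a 13-protofilament lattice templated on a ring of 13
γ-tubulins, with a 1.5-dimer helical pitch at the seam (seam contacts are
two half-strength overlaps). Each protofilament is a contiguous stack of
αβ-dimers. Events and their rates:

- **association** on each protofilament: `k_on · C` (C = free tubulin,
  held constant);
- **dissociation** of a terminal dimer: `k_off = k_on · exp(ΔG_tot / kBT)`
  with `ΔG_tot` the dimer's longitudinal bond (γ–αβ for the first layer,
  αβ–αβ above) plus its lateral contact weight times the lateral bond
  energy;
- **ring closure** (γ-TuRC only): the native complex is *open* and forbids
  lateral bonds; it may close at rate
  `k_conf · exp(−(ΔG_conf − n·|ΔG_lat|)/kBT)` where `n` is the lateral-bond
  weight the resident dimers would form on closure. Closure is irreversible
  and defines the nucleation time; the lattice occupancy at that instant is
  the transition state.

Under the cooperative model the early-time nucleation rate follows
`dN/dt|t→0 = k · N0 · C^n`, so the slope of ln(rate) against ln(C) measures
the critical nucleus *n*. Seeded assembly near the polymerization threshold
uses `dp/dt|t→0 ∝ C^(n−1)·(C − C*)` instead, with C* the critical
concentration from the growth-speed line `v = a·(C − C*)`. Cumulative MT
counts carry the Poisson field-to-field band `N ± 2√N`.

Baseline parameters: `k_on = 1.3e6 M⁻¹s⁻¹` per protofilament,
`ΔG_long,αβ-αβ = −7.2 kBT`, `ΔG_lat = −6.5 kBT`,
`ΔG_long,γ-αβ = 1.1 × (−7.2) kBT`, `k_conf = 0.01 s⁻¹`,
`ΔG_conf = 10 kBT`. An XMAP215 preset strengthens both longitudinal bonds
1.2-fold (`−8.64`, `−9.5`, lateral `−6.2 kBT`).

## Worked example

```python
from gturcsim import baseline_params, SimConfig, census
from gturcsim.pipeline import simulate_concentration_series, estimate_exponent_from_ensembles

cfg = SimConfig(mode="gturc", t_max=500.0, stop_after_nucleation=True)
ensembles = simulate_concentration_series(
    baseline_params(), [7, 10.5, 14, 21, 28], n_sims=200, master_seed=1, config=cfg
)
fit = estimate_exponent_from_ensembles(ensembles)
print(f"critical nucleus n = {fit.n:.2f} +/- {fit.stderr:.2f}")
summary = census(ensembles)
print(f"transition state: mean {summary.mean_total_dimers:.2f} dimers, "
      f"modal {summary.modal_cell}")
```

Output:

```
critical nucleus n = 4.01 +/- 0.14
transition state: mean 5.33 dimers, modal (4, 3.0)
```

Read: nucleation rate grows as roughly the 4th power of tubulin
concentration, i.e. ~4 dimers must assemble cooperatively on γ-TuRC before
the ring closes; at the instant of closure the template carries on average
~5 dimers, most often 4 neighbouring dimers sharing 3 lateral bonds.

The same machinery is available from the shell:

```bash
gturcsim ensemble --preset baseline --conc 10.5 --n-sims 200 --seed 1 --out ens.csv
gturcsim census --seed 1 --out census.json
gturcsim synth --regime gturc --n-true 3.9 --seed 1 --out table.csv
gturcsim estimate --mode gturc --in table.csv --out fit.json
```

Every command writes a manifest (parameters, seeds, file digests) next to
its output, and fixed seeds reproduce outputs bit-for-bit.

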