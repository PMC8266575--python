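# g4tweezers

Simulation and inference for single-molecule magnetic-tweezers force-ramp
experiments on polymorphic G-quadruplex (G4) DNA — in particular
parallel-stranded G4s whose tetrad core is interrupted by a bulge and which
therefore fold into several coexisting conformations: fully-folded G4s,
guanine-vacancy-bearing intermediates (GVBQs) with a peeled terminal
guanine, other partially-folded species, and unfolded/misfolded states.

It is written for single-molecule biophysicists who want to analyze
force-ramp pull-cycle data (or prototype such analyses on faithful synthetic
data): rupture-force tables in, fitted conformational ensembles out.

## What it computes

- **Bell ramp kinetics** — a folded state unfolds at rate
  `k(F) = k_u·exp(F·Δx‡/k_BT)`; under a linear ramp at rate `r` the
  rupture-force distribution has the closed Bell–Evans form with survival
  `S(F) = exp[−(k_BT·k_u)/(r·Δx‡)·(e^{FΔx‡/k_BT} − e^{F₀Δx‡/k_BT})]`,
  mode `F* = (k_BT/Δx‡)·ln[rΔx‡/(k_u·k_BT)]`, and exact inverse-CDF
  sampling.
- **Censored mixture MLE** — K-component Bell mixtures fit to rupture
  forces, with no-rupture-by-60-pN cycles entering as survival terms; peak
  forces, population fractions (per event and per cycle), zero-force rates,
  BIC model selection, posterior event assignment, bootstrap CIs.
- **Step sizes in nucleotides** — extension jumps converted at each event's
  rupture force through Marko–Siggia worm-like-chain ssDNA elasticity
  (`n = (Δx + d_fold)/l(F)`), plus a drift-immune change-point detector for
  raw extension traces.
- **Folding kinetics** — binomial MLE of
  `p_fold(t) = p_st·[1 − exp(−k_fold·t)]` from folded/unfolded counts per
  hold time, and the >40 pN / <40 pN stability split of `p_st`.
- **Sequence model** — annotated four-tract G4 designs (a packaged panel of
  27 bulged variants) with expected released-nucleotide counts per folding
  topology: fully-folded, 5′-peeled GVBQ, 3′-peeled GVBQ.
- **Melting curves** — sigmoid fits of normalized thermal-denaturation
  profiles; `Tm` at the inflection, affine-invariant in the signal.
- **Simulator** — the generative mirror of all of the above, with packaged
  scenarios encoding fitted multi-state ensembles as ground truth.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Simulate 5000 pull cycles of the three-state 5′-bulged ensemble and run the
whole analysis chain against the known truth:

```sh
g4tweezers report --scenario TB-1 --cycles 5000 --seed 7 --out report.json
```

The report (abridged) reads:

```
"truth_modal_forces_pN":  [22.0, 36.0, 47.0],
"truth_cycle_fractions":  [0.62, 0.25, 0.07],
"fitted" components:      modal forces 22.00, 35.92, 47.72 pN
"fitted_cycle_fractions": [0.616, 0.259, 0.067],
"steps" per component:    mean_step_nt 13.97, 13.31, 15.91
"kinetics":               truth p_st 0.94, k_fold 0.11 → fitted 0.916, 0.108
```

Reading it: from 4709 detected ruptures the censored mixture MLE recovers
all three unfolding-force peaks within ~0.7 pN and all three per-cycle
population fractions within 0.01; the dominant ~22 pN species releases
~14 nt (the 5′-peeled guanine-vacancy intermediate), the ~47 pN species
~15.9 nt (the fully-folded G4, spanning all twelve core guanines plus loops
and bulge); and the refolding series returns the fast apparent folding rate
(~0.1 s⁻¹) and high steady-state folding probability that characterize this
kinetically trapped intermediate-former.

The same components are available as a library:

```python
from g4tweezers import (load_scenario, simulate_cycles, forces_from_cycles,
                        fit_bell_mixture, fractions_of_cycles)

sc = load_scenario("TB-8")
cycles = simulate_cycles(sc.mixture, sc.protocol, sc.polymer, n_cycles=5000, seed=7)
forces, n_cens = forces_from_cycles(cycles)
fit = fit_bell_mixture(forces, n_cens, sc.protocol, K=2, seed=7)
print(fit.modal_forces)                  # [31.18 45.89] pN
print(fractions_of_cycles(fit, 5000))    # [0.339 0.623] of cycles
```

Other subcommands: `simulate`, `fit-forces` (with `--k-max` BIC scan),
`fit-pfold`, `stepsize` (trace detection or per-population summaries),
`melt`.  Constants (elasticity, protocol, noise) are YAML-overridable via
`--config`.

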