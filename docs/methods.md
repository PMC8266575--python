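# Methods

`g4tweezers` models a single-molecule magnetic-tweezers force-ramp experiment
on a DNA G-quadruplex (G4) tether and implements the inference chain that
turns its raw observables — rupture forces, extension jumps, refolding
outcomes, melting profiles — into the quantities a folding study reports:
peak unfolding forces, conformational population fractions, zero-force
unfolding rates, released-nucleotide counts per species, steady-state folding
probabilities, apparent folding rates, and melting temperatures.

## The experiment being modelled

A G4-forming sequence is held between dsDNA handles.  Each pull cycle drops
the force to ~1 pN for a hold time `t` (refolding window), then ramps the
force linearly (default 2 pN/s from 1 to 60 pN).  If the molecule folded
during the hold, the ramp produces a single abrupt extension increase at the
rupture force; if it stayed unfolded or misfolded, the trace is ssDNA-like
with no rupture.  Polymorphic sequences — here parallel G4s whose tetrad
core is interrupted by a 1–7 nt bulge — fold into several coexisting
conformations (fully-folded G4, guanine-vacancy intermediates with a peeled
terminal guanine, other partially-folded species), each with its own
mechanical fingerprint.

## Bell ramp kinetics (`bell`)

Each conformation is a Bell state: unfolding rate `k(F) = k_u·exp(F·Δx‡/kBT)`
with zero-force rate `k_u` (s⁻¹) and transition-state distance `Δx‡` (nm).
Under a deterministic linear ramp at rate `r` the rupture-force survival has
the closed Bell–Evans form

    S(F) = exp[−(kBT·k_u)/(r·Δx‡)·(e^{F·Δx‡/kBT} − e^{F₀·Δx‡/kBT})],

with density `p(F) = k(F)/r·S(F)`, analytic mode
`F* = (kBT/Δx‡)·ln[r·Δx‡/(k_u·kBT)]`, and exact inverse-CDF sampling.  The
force domain is used throughout (force and time are interchangeable on a
deterministic ramp).  Refolding during the seconds-long ramp is neglected.
Cycles that survive to the 60 pN ceiling are represented explicitly as
censored and contribute a survival factor to likelihoods.  The exponent `ν`
corrections of more elaborate rupture models are out of scope: the analysis
is single-loading-rate, where the Bell form is the standard choice.

A single peak force does not identify `(k_u, Δx‡)` jointly; packaged
scenarios therefore fix `Δx‡ = 1.0 nm` (the centre of the fitted box, and a
typical value for parallel G4 unfolding) and derive `k_u` by inverting the
mode.  At the default ramp a 55 pN peak maps to `k_u ≈ 7.5×10⁻⁷ s⁻¹` and a
46 pN peak to `≈ 6.7×10⁻⁶ s⁻¹`, i.e. the slow 10⁻⁵–10⁻⁷ s⁻¹ regime expected
for mechanically stable parallel G4s.

## ssDNA elasticity and step sizes (`polymer`, `steps`)

Unfolding a structure of `n` structured nucleotides at force `F` lengthens
the tether by `n·l(F) − d_fold`, where `l(F)` is the extension per ssDNA
nucleotide from the inextensible Marko–Siggia worm-like chain (numerically
inverted; persistence length 0.8 nm, contour 0.56 nm/nt) and `d_fold = 2 nm`
is the end-to-end extent of the folded structure along the pulling axis.
These constants are standard ssDNA literature values, exposed in config; the
stretch modulus is omitted because below 60 pN its effect is within the
measurement noise modelled here.  Each event's jump is converted to
nucleotides *at its own rupture force* and then averaged per population, so
nucleotide estimates are unbiased whether a species ruptures at 20 or 55 pN.
All nucleotide-valued checks are roundtrip-consistent by construction rather
than absolutely calibrated — the simulator and the analysis share the WLC.

Step detection in traces scans every candidate change point with a local
piecewise model `x = a + b·i + Δ·1[i ≥ k]` over two flanking windows
(default 25 samples each): the shared slope absorbs the smooth
handle-stretching drift of the ramp baseline, and the OLS step height `Δ̂`
is one fixed correlation kernel applied to the trace.  Candidates must
raise both `Δ̂` and the plain window-mean difference (vetoing sign-flipped
artifacts next to downward transients); the noise scale is estimated
robustly from first differences, and the single maximal upward step is
reported if `Δ̂/SE ≥ min_snr` (default 5, giving <1% false positives on
pure-noise traces).  One step per ramp is assumed; multi-step traces yield
the largest.

## Sequence model (`sequences`)

The studied designs are four-tract parallel G4s written with space-separated
tracts (e.g. `TTGTGGT GGGT GGGT GGGT`): twelve tetrad-core guanines, thymine
loops and flanks, and at most one thymine bulge interrupting one of the
eight successive guanine pairs of the core columns.  The expected released
nucleotide count of a topology is the inclusive span between the outermost
*structured* core guanines — loops and internal bulges count, dangling tails
do not: fully folded = last − first + 1; 5′-peeled guanine-vacancy (GVBQ) =
last − second + 1; 3′-peeled = second-to-last − first + 1.  This single
convention reproduces 16 nt (fully-folded 5′- and 3′-bulged designs), 14 nt
(their peeled intermediates), and 15 nt (bulge-free control) without extra
parameters.  The ~13 nt minor intermediate is not assigned a topology (none
is established); it is representable as a free `step_nt` on a Bell state.

## Simulator (`simulate`, `scenarios`)

The generator mirrors the measurement: per cycle a categorical draw over the
state mixture (including an unfolded/misfolded outcome that produces no
rupture — mechanically weak species that would unfold below ~4 pN are merged
into this class since their steps are undetectable), exact inverse-CDF
rupture forces, WLC forward-model jumps with Gaussian noise (default
σ_step = 0.6 nm, typical bead-tracking accuracy), binomial refolding
outcomes under `p_fold(t) = p_st[1 − e^{−k_fold t}]`, optional full traces
(dsDNA-handle baseline, default 1700 bp, plus per-sample bead noise at
100 Hz), and sigmoidal melting profiles on a 20–85 °C grid.  State identity
is redrawn independently each cycle: cycles are pooled across molecules in
the analysis, so per-molecule kinetic partitioning is not modelled.  Same
seed ⇒ bit-identical output, and truth labels ride along for scoring.

Packaged scenarios encode fitted ensembles as simulation truth.  Weights are
fractions of cycles and sum to 1 with the unfolded weight; the folded-state
weights sum to the steady-state folding probability.  Headline scenarios:
the 5′-bulged three-state ensemble (peaks ~22/36/47 pN, cycle fractions
62/25/7%, p_st 0.94, k_fold 0.11 s⁻¹), the 3′-bulged two-state ensemble
(~31/46 pN, 33/63%, p_st 0.96), a middle-bulge design dominated by the
fully-folded form (~55 pN, p_st 0.69, k_fold 0.02 s⁻¹), longer-bulge and
peptide-conjugate-shifted variants, and melting scenarios at 48/44/36 °C.
Where a printed source value does not exist (the bulge-free control's
fractions, minor-peak weights, step counts of unassigned species), the
scenario uses a representative value chosen once and documented in the YAML
description.

## Mixture fitting (`mixture`)

Rupture forces are fit by censored maximum likelihood over a K-component
Bell mixture:

    L = Σ_j log Σ_i w_i p_i(F_j) + n_cens·log Σ_i w_i S_i(F_end).

MLE on raw forces is bin-free and censoring-aware; a histogram least-squares
mode is kept for parity with binned-distribution figures and agrees with the
MLE peaks within 1 pN at large n.  Parameterization is `(ln k_u, Δx‡)` per
component with `Δx‡ ∈ [0.2, 5] nm` — the box tames the strong `k_u–Δx‡`
anticorrelation of single-rate data — and weights through a softmax.
Optimization is L-BFGS-B with the analytic gradient (responsibilities times
per-component scores), started from a deterministic 1-D k-means split with
Gumbel moment matching (the ramp distribution has scale `kBT/Δx‡`, so
`Δx‡ ≈ kBT·π/(σ√6)`) plus nine jittered restarts.  `select_K` scans
K = 1..K_max by BIC (ties to fewer components).  Percentile bootstrap CIs
come from case resampling of cycles with warm-started refits.

Fractions are reported in two conventions, and conflating them is the main
pitfall when comparing percentages: mixture weights are fractions of
*folded* outcomes (events + censored), while per-peak percentages that sum
to the folding probability are fractions of *cycles* (weights × folded-cycle
fraction).  `population_fractions` splits mixture mass at a modal-force
threshold (default 40 pN, the stable/partially-folded divide) and also
reports the empirical event-count split; `fractions_of_cycles` converts to
the cycle convention.

## Folding kinetics (`kinetics`) and melting (`melting`)

Folded/unfolded counts per hold time are binomial with heteroscedastic,
small-sample noise, so `(p_st, k_fold)` is fit by binomial MLE (multi-start
on `k_fold`) with standard errors from the finite-difference observed
information; `t` is the programmed hold time at the low force, ramp duration
excluded.  Pooled fitting is the default; a replicated-tether mode fits each
tether and reports mean ± SD, mirroring per-tether averaging.  All-zero or
all-saturated counts are flagged non-identifiable rather than fit.
`split_pst_by_stability` apportions the folded fraction by the 40 pN event
threshold (censored cycles count as stable).

Melting profiles are fit with a phenomenological logistic in temperature
(nonlinear least squares, multi-start on the midpoint); `Tm` is the
inflection.  The model is affine in the two baselines, so `Tm` is invariant
to affine rescaling of the signal — raw and normalized profiles give the
same answer, which is why a two-state van 't Hoff parameterization is not
needed for `Tm` extraction.  Flat profiles (amplitude within 3× the
residual noise) are flagged non-identifiable; sloping baselines are off by
default (profiles are assumed normalized).

## Numerical and testing choices

- WLC inversion: Brent to machine tolerance; roundtrip nt→nm→nt errors
  < 1e-9 over the full working range.
- Mixture fits on 5000-event datasets take ~1 s; recovery tests and the
  reproduction script use 5000 cycles per scenario, 6 hold times × 120
  cycles for kinetics, and 1 °C melting grids — the scale of the emulated
  experiments.
- The folding-kinetics tolerance (p_st within ±0.03 at 720 cycles) is about
  two standard errors for one simulated series, so recovery tests assert the
  median error over three replicate series at that scale instead of a single
  draw.
- Degenerate inputs fail loudly: censored-only force data (no finite MLE),
  fewer than 5K events per K components, single hold times, flat melting
  curves, traces shorter than two windows.

## What the generator does and does not emulate

The simulator reproduces the statistical structure of the measurement —
mixture-distributed rupture forces with censoring, WLC-consistent jump
sizes, binomial refolding, sigmoidal melting — so passing recovery tests
demonstrates that the inference chain is consistent and well-calibrated *for
data of that structure*.  It does not model drift, camera/tracking
artifacts, bead rotation, force-calibration error, molecule-to-molecule
parameter variability, refolding during the ramp, or multi-step unfolding;
agreement on synthetic data therefore bounds estimator error, not
instrumental systematics.  Absolute nucleotide calibration additionally
inherits whatever uncertainty the chosen elasticity constants carry on a
real instrument.
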