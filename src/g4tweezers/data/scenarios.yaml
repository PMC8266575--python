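# Packaged simulation scenarios: each encodes the fitted conformational
# ensemble of one G4 design as simulation truth (peak rupture forces at the
# 2 pN/s ramp, per-cycle population fractions, released-nucleotide counts,
# and refolding kinetics).  A single peak force does not pin down
# (k_unfold, dx) jointly, so scenarios fix dx (nm) and derive k_unfold by
# inverting the modal-force relation at load time.
#
# Weight convention: state weights plus w_unfolded are fractions of pull
# cycles and sum to 1; the folded-state weights sum to the steady-state
# folding probability p_st.

defaults:
  protocol:
    f_start: 1.0
    f_end: 60.0
    loading_rate: 2.0
    hold_force: 1.0
    hold_time: 30.0
    kBT: 4.11
  polymer:
    persistence_length_nm: 0.8
    contour_per_nt_nm: 0.56
    folded_extent_nm: 2.0
    kBT_pN_nm: 4.11
  noise:
    sigma_step_nm: 0.6
    sigma_bead_nm: 1.0
    trace_rate_hz: 100.0
  dx_nm: 1.0

scenarios:
  T30695:
    description: >-
      Bulge-free parallel G4 control: one dominant mechanically stable
      species near 55 pN plus a minor weak species.  Fractions and kinetics
      are representative defaults for a canonical parallel G4.
    sequence: T30695
    states:
      - {label: intermediate, modal_force_pN: 16.0, step_nt: 13, weight: 0.08}
      - {label: full, modal_force_pN: 55.0, step_nt: 15, weight: 0.65}
    w_unfolded: 0.27
    kinetics: {p_st: 0.73, k_fold_per_s: 0.03}

  TB-1:
    description: >-
      1-nt bulge at guanine pair 1 (5'-proximal).  Three folded species:
      a dominant 5'-peeled guanine-vacancy intermediate (~22 pN, 14 nt), a
      second partially-folded intermediate (~36 pN, 13 nt), and the
      fully-folded G4 (~47 pN, 16 nt); fast refolding.
    sequence: TB-1
    states:
      - {label: gvbq_5p, modal_force_pN: 22.0, step_nt: 14, weight: 0.62}
      - {label: intermediate, modal_force_pN: 36.0, step_nt: 13, weight: 0.25}
      - {label: full, modal_force_pN: 47.0, step_nt: 16, weight: 0.07}
    w_unfolded: 0.06
    kinetics: {p_st: 0.94, k_fold_per_s: 0.11}

  TB-2:
    description: >-
      1-nt bulge at guanine pair 2 (middle-type behaviour): dominant
      fully-folded species near 55 pN, minor weak species near 16 pN,
      larger unfolded/misfolded fraction and slow refolding.
    sequence: TB-2
    states:
      - {label: intermediate, modal_force_pN: 16.0, step_nt: 14, weight: 0.09}
      - {label: full, modal_force_pN: 55.0, step_nt: 16, weight: 0.60}
    w_unfolded: 0.31
    kinetics: {p_st: 0.69, k_fold_per_s: 0.02}

  TB-8:
    description: >-
      1-nt bulge at guanine pair 8 (3'-proximal).  Two folded species: a
      3'-peeled guanine-vacancy intermediate (~31 pN, 14 nt) and the
      fully-folded G4 (~46 pN, 16 nt).
    sequence: TB-8
    states:
      - {label: gvbq_3p, modal_force_pN: 31.0, step_nt: 14, weight: 0.33}
      - {label: full, modal_force_pN: 46.0, step_nt: 16, weight: 0.63}
    w_unfolded: 0.04
    kinetics: {p_st: 0.96, k_fold_per_s: 0.10}

  T3B-1:
    description: >-
      3-nt bulge at guanine pair 1: the longer 5' bulge suppresses the
      fully-folded form; two partially-folded species (~20 pN and ~36 pN,
      both guanine-vacancy-like with ~14 and 13 nt steps).
    sequence: T3B-1
    states:
      - {label: gvbq_5p, modal_force_pN: 20.0, step_nt: 14, weight: 0.55}
      - {label: intermediate, modal_force_pN: 36.0, step_nt: 13, weight: 0.35}
    w_unfolded: 0.10
    kinetics: {p_st: 0.90, k_fold_per_s: 0.10}

  TB-1-GRPC:
    description: >-
      TB-1 in the presence of a saturating guanine-peptide conjugate that
      fills the guanine vacancy: the ~22 pN intermediate shifts to ~53 pN
      while the ~36 pN intermediate is retained (~33 pN peak); overall
      folding probability is reduced.
    sequence: TB-1
    states:
      - {label: intermediate, modal_force_pN: 33.0, step_nt: 13, weight: 0.35}
      - {label: gvbq_grpc, modal_force_pN: 53.0, step_nt: 14, weight: 0.45}
    w_unfolded: 0.20
    kinetics: {p_st: 0.80, k_fold_per_s: 0.05}

  T3B-1-GRPC:
    description: >-
      T3B-1 with the guanine-peptide conjugate: peaks near 40 and 55 pN.
    sequence: T3B-1
    states:
      - {label: intermediate, modal_force_pN: 40.0, step_nt: 13, weight: 0.35}
      - {label: gvbq_grpc, modal_force_pN: 55.0, step_nt: 14, weight: 0.45}
    w_unfolded: 0.20
    kinetics: {p_st: 0.80, k_fold_per_s: 0.05}

melting_scenarios:
  top-tetrad: {tm_C: 48.0, width_C: 3.0}
  bottom-tetrad: {tm_C: 44.0, width_C: 3.0}
  middle-tetrad: {tm_C: 36.0, width_C: 3.0}
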