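# Default calibration for hsrkit (version 1).
#
# All tunable constants live here: the ODE parameter set used as the
# wild-type baseline, the default stress protocols, and the ground-truth
# constants of the synthetic-data generators.  Analysis code loads this file
# through hsrkit.calibration; nothing hard-codes these numbers.
version: 1

model:
  # Basal misfolded-client influx is essentially zero in unstressed cells;
  # the stress multipliers therefore carry the entire stress load
  # (s * k_U0 = 4.5 a.u./min under heat, 4.0 under 8.5% ethanol).
  k_U0: 1.0e-07    # basal client production, a.u./min (negligible pre-stress)
  s_heat: 4.5e+07  # fold-increase of client influx at 39 C
  s_eth: 4.0e+07   # fold-increase of client influx at 8.5% ethanol
  k_bU: 1.0        # Hsp70-client association, 1/(a.u. min)
  k_rel: 0.05      # productive client release, 1/min (auxiliary feedback)
  k_offU: 0.005    # non-productive release, 1/min (0.1 x k_rel)
  k_bF0: 10.0      # maximal Hsp70-Hsf1 association, 1/(a.u. min)
  k_uF: 1.0        # Hsp70-Hsf1 dissociation, 1/min
  K_sis: 1.0       # client level at half-maximal affinity switch, a.u.
  h_sis: 3.0       # affinity-switch Hill coefficient
  beta0: 0.02      # basal Hsp70 synthesis, a.u./min
  beta1: 2.2       # maximal Hsf1-dependent Hsp70 synthesis, a.u./min
  K_hsf: 0.012     # Hill constant of Hsp70 induction, a.u. (near basal free Hsf1)
  n_hsf: 4.0       # steep, so Hsp70 stays induced with little extra Hsf1 activity
  alpha_y: 1.0     # maximal HSE-YFP transcription, a.u./min
  K_y: 0.1         # Hill constant of the reporter promoter, a.u.
  n_y: 1.4         # shallow reporter response (broad dynamic range)
  m_mat: 0.05      # YFP maturation, 1/min (~14 min half-time)
  gamma: 0.0025    # dilution/degradation, 1/min (~4.6 h doubling in stress)
  F_tot: 1.0       # total Hsf1, a.u.

protocols:
  heat:
    magnitude_c: 39.0
    t_on_min: 0.0
    sample_times_min: [0, 15, 30, 45, 60, 90, 120, 150, 180, 240]
  ethanol:
    magnitude_pct: 8.5
    t_on_min: 0.0
    sample_times_min: [0, 15, 30, 45, 60, 90, 120, 150, 180, 240]

synthetic:
  regulon:
    n_genes: 42
    times_min: [0, 15, 30, 45, 60, 90, 120, 150, 180, 240]
    basal_min: 10.0          # a.u.; library spans basal_decades above this
    basal_decades: 4.0
    fold_change_min: 1.05
    fold_change_max: 10.0
    t50_min: 20.0            # min
    t50_max: 180.0
    rate_scale: 6.0          # logistic rate k ~ rate_scale / t50 (curves rise from baseline)
    rate_jitter_sigma: 0.15  # lognormal jitter on k
    rho_fc_t50: -0.7         # rapid genes induce more
    rho_basal_fc: -0.75      # high-basal genes induce weakly
    replicate_cv: 0.05
    n_replicates: 3
  ethanol_panel:
    concentrations_pct: [0, 2, 4, 5, 6, 6.5, 7, 7.5, 8, 9, 10, 12, 14]
    times_min: [0, 15, 30, 45, 60, 90, 120, 150, 180, 240]
    ec50_yfp_pct: 6.9        # true EC50 of reporter activation
    hill_n_yfp: 6.0
    yfp_floor_fold: 1.0
    yfp_ceiling_fold: 15.0
    ic50_growth_pct: 6.6     # true IC50 of growth inhibition
    hill_n_growth: 6.0
    growth_floor_rel: 0.1    # residual relative growth at saturating ethanol
    sigmoid_min_conc_pct: 6.0  # time courses sigmoidal at/above this dose
    replicate_cv: 0.05
    n_replicates: 3
  flow:
    ssc_sigma: 0.5           # lognormal sigma of side scatter (cell size)
    ratio_sigma: 0.12        # residual per-cell noise after size removal
    dead_fraction: 0.0
    dead_fluor_atten: 0.05   # dead cells lose most fluorescence
    dead_ssc_atten: 0.3      # ...and shrink in side scatter
  growth:
    od0: 0.1
    carrying_capacity: 1.0
    rate_phase1: 0.004       # 1/min at 30 C
    rate_phase2: 0.007       # 1/min at 37 C, unstressed
    shift_min: 240.0         # 30->37 C shift after 4 h
    total_min: 1440.0        # 24 h
    sampling_min: 20.0
    replicate_cv: 0.01       # plate-reader OD noise
    n_replicates: 2
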