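# Universal parameter sets for the COSMO-SAC (2002) and COSMO-SAC-HB2
# activity-coefficient models, one preset per quantum-chemistry level
# (BP-TZVPD-FINE, BP-TZVP, HF-TZVP).  Hydrogen-bond constants C_HB* are in
# kcal mol^-1 A^4 e^-2; sigma_hb in e/A^2; radii in A.

constants:
  eps0: 2.395e-4            # e^2 mol kcal^-1 A^-1
  gas_constant: 1.98721e-3  # kcal mol^-1 K^-1
  z_coordination: 10.0
  r0_volume: 66.69          # A^3, Staverman-Guggenheim volume normalizer
  q0_area: 79.53            # A^2, Staverman-Guggenheim area normalizer

# Donor class -> acceptor class -> HB constant name (HB2 variant).
# Water and hydroxyl donors/acceptors get dedicated constants; nitrogen and
# other (ether/carbonyl) acceptors share one constant per donor type.
hb_pair_map:
  WATER_DONOR:
    WATER_ACCEPTOR: C_HB
    OH_ACCEPTOR: C_HB2
    N_ACCEPTOR: C_HB5
    OTHER_ACCEPTOR: C_HB5
  OH_DONOR:
    WATER_ACCEPTOR: C_HB3
    OH_ACCEPTOR: C_HB4
    N_ACCEPTOR: C_HB6
    OTHER_ACCEPTOR: C_HB6
  NH_DONOR:
    WATER_ACCEPTOR: C_HB7
    OH_ACCEPTOR: C_HB7
    N_ACCEPTOR: C_HB8
    OTHER_ACCEPTOR: C_HB8

presets:
  HB2-FINE:
    variant: hb2
    f_pol: 0.9987
    r_avg: 1.5000
    r_eff: 1.1781
    sigma_hb: 7.01e-3
    c_hb:
      C_HB: 8263.93
      C_HB2: 16061.92
      C_HB3: 7496.26
      C_HB4: 16989.74
      C_HB5: 25332.78
      C_HB6: 12882.18
      C_HB7: 28400.07
      C_HB8: 19668.59
  HB2-BP-TZVP:
    variant: hb2
    f_pol: 0.7560
    r_avg: 1.5000
    r_eff: 1.2806
    sigma_hb: 7.03e-3
    c_hb:
      C_HB: 8400.52
      C_HB2: 17251.80
      C_HB3: 11123.03
      C_HB4: 17575.78
      C_HB5: 23721.46
      C_HB6: 12733.48
      C_HB7: 28538.48
      C_HB8: 12978.83
  COSMO-SAC-FINE:
    variant: cosmosac2002
    f_pol: 0.8893
    r_avg: 1.6000
    r_eff: 1.2547
    sigma_hb: 1.15e-2
    c_hb: 181543.18
  HB2-HF-TZVP:
    variant: hb2
    f_pol: 0.7817
    r_avg: 1.1000
    r_eff: 1.1567
    sigma_hb: 7.70e-3
    c_hb:
      C_HB: 15020.48
      C_HB2: 14171.02
      C_HB3: 9327.21
      C_HB4: 14171.02
      C_HB5: 14171.02
      C_HB6: 6866.67
      C_HB7: 4642.64
      C_HB8: 14171.02
  COSMO-SAC-HF-TZVP:
    variant: cosmosac2002
    f_pol: 0.8041
    r_avg: 1.4000
    r_eff: 1.1565
    sigma_hb: 1.01e-2
    c_hb: 58250.49

aliases:
  SAC-FINE: COSMO-SAC-FINE
  SAC-HF-TZVP: COSMO-SAC-HF-TZVP
  FINE: HB2-FINE
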