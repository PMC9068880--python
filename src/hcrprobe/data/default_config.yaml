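# Default configuration for hcrprobe.
#
# Amplifier split-initiator arms for the five standard HCR v3.0 amplifiers
# (B1-B5), transcribed from the published v3.0 amplifier initiator
# definitions: each 36-nt initiator is split into an 18-nt upstream half
# (appended 5' of the P1 binding region) and an 18-nt downstream half
# (appended 3' of the P2 binding region).  If your amplifier stocks use the
# opposite arm placement, swap initiator_up / initiator_down here.
amplifiers:
  B1:
    initiator_up: GAGGAGGGCAGCAAACGG
    initiator_down: GAAGAGTCTTCCTTTACG
  B2:
    initiator_up: CCTCGTAAATCCTCATCA
    initiator_down: ATCATCCAGTAAACCGCC
  B3:
    initiator_up: GTCCCTGCCTCTATATCT
    initiator_down: CCACTCAACTTTAACCCG
  B4:
    initiator_up: CCTCAACCTACCTCCAAC
    initiator_down: TCTCACCATATTCGCTTC
  B5:
    initiator_up: CTCACTCCCAATCTCTAT
    initiator_down: CTACCCTACAAATCCAAT

# Linker between each initiator arm and the binding region (both sides).
arm_spacer_up: AA
arm_spacer_down: AA

# Hybridization buffer the probes must tolerate.
conditions:
  temperature_c: 37.0
  na_molar: 1.0
  formamide_pct: 30.0

# Screening and selection parameters.
parameters:
  probe_len: 25
  spacer_len: 2
  max_pairs: 36
  region_priority: [ORF, UTR3, UTR5]
  gc_min: 0.25
  gc_max: 0.75
  tm_margin_c: 5.0
  max_homopolymer: 4
  max_hits: 1
  max_mismatches: 2
  seed_k: 11
  probe_conc_molar: 5.0e-9
  formamide_coeff_c_per_pct: 0.65
  salt_correction: santalucia   # or: owczarzy
  keep_unmapped: false
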