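# Demo pipeline configuration: simulate a separated 3-class cohort and run
# the full workflow (SREM fit, class enumeration G=1..3, selection, dynamic
# prediction, AUC comparison).  Re-running with the same seed reproduces
# every CSV byte for byte.
outdir: trajsurv_demo_output
simulate:
  generator: JLCM
  truth: separated
  n_subjects: 250
g_range: [1, 2, 3]
n_starts: 3
seed: 1
window: 3.0
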