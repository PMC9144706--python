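# Example configuration.
#
# The two scenarios are PLACEHOLDER laboratory workloads: their absolute
# exposure parameters are illustrative (every laboratory must characterise
# its own panel's workload), but their CDI-multiplier ratio (~5.52)
# reproduces the commercial-vs-institutional risk ratio observed in
# published refinery-campaign assessments.
scenarios:
  - label: commercial
    et: 3      # hours/day of panel exposure
    ef: 221    # analysis days/year
    ed: 25     # years on the panel
    lt: 70     # lifetime, years (carcinogenic averaging basis)
  - label: institutional
    et: 2
    ef: 60
    ed: 25
    lt: 70
criteria:
  hi_max: 1.0
  ir_mixture_max: 1.0e-5
  ir_single_max: 1.0e-6
# 14-step factor-2 ladder starting at 1:4 (the package default); uncomment
# to override.
# ladder: [4, 8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192, 16384, 32768]
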