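# Default quality thresholds.
#
# These are COHORT-SPECIFIC values published for a multicentre paediatric
# dataset of 1027 reviewer-labelled signal-time courses.  They are shipped
# as a convenient starting point only; recalibrate on your own labelled
# data with `dscqc calibrate` before relying on them.
sdnr_min: 7.6
rmse_max: 0.019
fwhm_range: [3.0, 19.0]
psr_range: [42.9, 130.4]
k: 0
per_fold: []
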