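# Five predefined threshold sets spanning the sensitivity/specificity range.
# step_height is in units of the 90th-percentile normalization value (Q_min);
# step_factor and enrichment_factor are dimensionless ratios; the *_reduction
# values are subtracted from the corresponding thresholds when re-evaluating
# replicates that missed a TSS detected elsewhere.
#
# This table is deliberately a single editable file: sites that calibrate
# against their own protocol can adjust it without touching code.
very_sensitive:
  step_height: 0.1
  step_factor: 1.5
  enrichment_factor: 1.5
  height_reduction: 0.05
  factor_reduction: 0.3
sensitive:
  step_height: 0.2
  step_factor: 1.5
  enrichment_factor: 1.5
  height_reduction: 0.1
  factor_reduction: 0.5
default:
  step_height: 0.3
  step_factor: 2.0
  enrichment_factor: 2.0
  height_reduction: 0.2
  factor_reduction: 0.5
specific:
  step_height: 0.5
  step_factor: 2.0
  enrichment_factor: 2.0
  height_reduction: 0.3
  factor_reduction: 1.0
very_specific:
  step_height: 1.0
  step_factor: 3.0
  enrichment_factor: 3.0
  height_reduction: 0.5
  factor_reduction: 2.0
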