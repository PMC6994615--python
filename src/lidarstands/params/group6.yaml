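segmentation:
  gradient_band_weights: &id001
  - 0.4
  - 0.3
  - 0.2
  region_growing_band_weights: *id001
  priority_function:
  - 0.0
  - 0.1
  - 0.2
  - 0.3
  - 0.5
  - 0.7
  - 1.0
  competition_threshold: 0.04
merging:
  band_weights: *id001
  rounds:
  - mean:
    - 0.05
    - 1.0
    - 2.0
    std:
    - 0.0
    - 1.0
    - 0.2
  - mean:
    - 0.1
    - 1.5
    - 2.5
    std:
    - 0.008
    - 1.5
    - 0.4
  - mean:
    - 0.15
    - 1.8
    - 3.0
    std:
    - 0.015
    - 1.8
    - 0.6
  - mean:
    - 0.2
    - 2.0
    - 3.2
    std:
    - 0.02
    - 2.0
    - 0.75
  maximum_area: 50000
  small_segment_area: 500
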