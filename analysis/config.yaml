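# Study configuration for the analysis scripts: 24 synthetic fires drawn
# round-robin from conifer-dominated / mixed / aspen-rich landscape strata.
# Heavy per-fire artifacts (rasters, detections) go under scratch/; the
# scripts write their summary tables to results/.
seed: 1
n_fires: 24
out_dir: scratch/run
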