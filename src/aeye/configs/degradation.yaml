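# Rate x resolution degradation grid on a synthetic dataset.
n_videos: 24
class_ratio: 0.5
patients: 4
eccentric_fraction: 0.25
duration: 6.0
rate: 60.0
resolution: [60, 80]
dataset_seed: 7
betas: [0.25]
windows: [null]
backbone: tiny_mlp
epochs: 30
train_seed: 7
voting_methods: [soft]
run_length: 50
threshold: 0.5
test_fraction: 0.25
degradation_rates: [60, 30, 15]
degradation_resolutions: [[60, 80], [15, 20]]
output_dir: aeye_degradation
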