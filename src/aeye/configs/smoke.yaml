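# Minutes-scale CPU smoke run: tiny dataset, default backbone, soft voting.
n_videos: 16
class_ratio: 0.5
patients: 4
eccentric_fraction: 0.25
duration: 4.0
rate: 60.0
resolution: [48, 64]
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
degradation_rates: []
degradation_resolutions: []
output_dir: aeye_smoke
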