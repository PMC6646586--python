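action_set: STD
dt: 0.1
episode_length: 40
init_mode: gabor
n_atoms: 200
n_checkpoints: 10
n_stimuli: 10
policy: learned
scales: both
seed: 0
texture_side: 600
total_iterations: 50000
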