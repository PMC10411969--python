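# Example configuration for `mirrorcode run --config examples/config.yaml`.
# Omitted keys fall back to the analysis defaults (alpha 0.05, bootstrap
# n_boot 1000, permutation n_perm 250 with in-null bootstrap 200,
# o2o-accuracy thresholds 5-15 percentage points).

out_dir: mirrorcode_out
seed: 1

simulate:
  n_neurons: 60
  trials_per_condition: 64
  rate_base: 10.0          # Hz, action-independent floor
  rate_effect: 20.0        # Hz added for the preferred action in coding bins
  epoch_modulation: 20.0   # Hz added over the action-period epochs, both tasks
  coding_window: [1, 4]    # bins, length range of the planted coding window
  profile_mix:
    shared: 0.2
    non_shared: 0.5
    obs_only: 0.1
    non_coding: 0.2

# To analyse a trials table instead of simulating, replace `simulate:` with
#   input_path: path/to/population.csv
# (columns: neuron_id, trial_id, task, action, the eight *_ms event columns,
#  spikes_ms as a JSON array).
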