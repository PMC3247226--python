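# Benchmark sweep configuration for `regnann bench`.
#
# `base` holds settings shared by every cell; each entry under `cells`
# overrides part of it and becomes one ProtocolConfig.  Every field of
# ProtocolConfig can appear in either place; `learning` nests the
# back-propagation hyper-parameters (LearningParams fields).
#
# This example runs two miniature sweeps at desk scale: network recovery
# as a function of the data ratio (samples per gene) on scale-free
# trees, and as a function of the training epochs.

base:
  topology_model: barabasi        # or erdos_renyi (+ mean_degree)
  topology_params: {power: 1.0, edges_per_step: 1}
  n_nodes: 12
  normalization: linear_rescaled  # raw | linear_rescaled | statistical | discretized
  threshold: 0.5
  score: mcc                      # or auc_mr (threshold-free)
  n_data_repeats: 2               # independent data draws per topology
  n_topologies: 2                 # independently sampled topologies
  base_seed: 5
  learning: {learning_rate: 0.01, momentum: 0.8, epochs: 200}

cells:
  # recovery improves with samples per gene
  - {data_ratio: 0.5}
  - {data_ratio: 1.0}
  - {data_ratio: 2.0}
  # recovery as a function of training epochs at fixed ratio
  - {data_ratio: 1.0, learning: {epochs: 50}}
  - {data_ratio: 1.0, learning: {epochs: 400}}
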