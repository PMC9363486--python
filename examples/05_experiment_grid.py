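"""A miniature experiment grid with the aggregation used for benchmarks.

Enumerates (dataset x setup x fraction x focal class) cells, trains one
small capsule model per cell, and reports AUROC as mean +/- std over the
focal classes with the best and second-best scores flagged.
"""

from capsanomaly import (
    NetworkConfig,
    aggregate,
    generate_synthetic_images,
    report,
    run_grid,
)

images, labels = generate_synthetic_images(n_classes=2, n_per_class=150, seed=3)
cfg = NetworkConfig(n_parallel_layers=4, n_filters=4, secondary_dim=8)

result = run_grid({"synthetic": (images, labels)},
                  setups=["diverse_outlier"], fractions=[0.2],
                  classes=[0, 1], seed=11, network_config=cfg, epochs=3)

print(result.table.head())
print()
print(report(aggregate(result.table)))
# Each row aggregates the per-focal-class AUROCs for one score; ** and *
# mark the best and second-best mean within a condition.
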