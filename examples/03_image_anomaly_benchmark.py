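"""Supervised anomaly detection on the parts-composed image fixture.

Runs a scaled-down version of the reference image benchmark: 500 normal +
50 anomalous 16x16 images, a capsule network trained for 5 epochs, all six
capsule scores plus the NL and ABC baselines evaluated on held-out data.
Expect roughly a minute on one CPU; the full-size run (2000 + 200, 10
epochs) is image_benchmark() with its defaults.
"""

from capsanomaly.benchmarks import image_benchmark

result = image_benchmark(seed=42, epochs=5, n_per_class=500)

print(f"train examples: {result['n_train']}, held-out: {result['n_test']}")
print("orientation fitted on training data:", result["orientation"])
print(result["table"].round(4))

# auroc: probability that a random anomaly outranks a random normal example
# (1.0 = perfect detection, 0.5 = chance). gini/palma score each example by
# the inequality of its routing couplings into the anomaly-class capsule;
# plain is the network's anomaly-class probability; nl/abc are the
# reconstruction-error baselines.
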