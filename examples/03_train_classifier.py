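"""Train a reduced frequency-pyramid classifier on synthetic gaits.

Uses half the shipped benchmark (50 sequences per class, 20 epochs) so the
script finishes in roughly two minutes on one CPU; the acceptance script
runs the full 100-per-class version.
"""

from gaitfreq import benchmark as bm
from gaitfreq import evaluate_model, train_model

data = bm.make_benchmark(n_per_class=50, seed=0)
print(f"{len(data)} sequences, classes: {', '.join(bm.BENCHMARK_CLASSES)}")

result = train_model(
    bm.benchmark_model_config("fpgcn"),
    data,
    bm.benchmark_train_config(seed=0, epochs=20),
)

print(result.history.tail(3).to_string(index=False))
print(f"best validation epoch: {result.best_epoch}")
print(f"held-out test accuracy: {result.test_accuracy:.3f}")

# per-class one-vs-rest accuracies on the test split
report = evaluate_model(result.model, result.splits[2])
print("micro accuracy:", round(report.micro, 3),
      "| macro (class-mean one-vs-rest):", round(report.macro, 3))
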