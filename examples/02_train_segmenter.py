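"""Train the improved UNet variant on a small phantom set and report mIoU.

Kept deliberately small (100 slices, 14 epochs) so it finishes in about
two minutes on one CPU; the full desk-scale benchmark (200 slices, 18 epochs)
lives in scripts/acceptance.py.
"""

from apexseg.arch import variant_spec
from apexseg.benchmarks import (benchmark_model_spec, benchmark_train_config,
                                easy_benchmark_config)
from apexseg.phantom import generate_dataset
from apexseg.training import train

train_set, test_set = generate_dataset(100, easy_benchmark_config(), seed=5)
spec = variant_spec("improved", benchmark_model_spec())
params, log = train(spec, train_set,
                    benchmark_train_config(seed=1, epochs=14),
                    val_set=test_set)

for entry in log:
    print(f"epoch {entry['epoch']:2d}  loss {entry['loss']:.4f}  "
          f"val mIoU {entry['val_miou']:.4f}")
print()
print("The loss is cross-entropy + soft Dice; val mIoU is the mean IoU of")
print("the three foreground structures (OC, ICA, SS) on the held-out 20%.")
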