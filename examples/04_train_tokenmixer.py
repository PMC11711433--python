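"""Train a width-reduced TokenMixer on a separable synthetic 2-class set.

Generates 100 images per class of two well-separated subtypes (FI benign,
DU malignant), splits 64/16/20, and trains for 20 epochs with the study's
augmentation settings.  The final training accuracy should reach 1.0 within
a few epochs - the classes are separable by construction - and the held-out
test metrics print at the end.
"""

from pathlib import Path

from tokenmixer import (AugmentationConfig, SyntheticSpec, TokenMixerConfig,
                        TrainConfig, build_tokenmixer, evaluate,
                        generate_dataset, load_records, stratified_split,
                        train)

data = Path("example_output/separable")
spec = SyntheticSpec(counts={(200, "FI"): 100, (200, "DU"): 100}, seed=7)
generate_dataset(spec, data)
records = load_records(data)
split = stratified_split(records, seed=7)
print(f"train/val/test: {len(split.train)}/{len(split.validation)}/{len(split.test)}")

cfg = TokenMixerConfig(image_size=56, embed_dim=32, key_dim=16, heads=2,
                       layers=2, mlp_units=(32,), head_units=(64,),
                       dropout=0.0, head_dropout=0.0, n_classes=2)
handle = build_tokenmixer(cfg, seed=7)
history, timing = train(handle, split, TrainConfig(epochs=20, seed=7),
                        AugmentationConfig())
print("train accuracy by epoch:", [round(a, 3) for a in history["accuracy"][:8]], "...")
print(f"total training time {timing.total_training_time_s:.1f}s, "
      f"avg/epoch {timing.avg_time_per_epoch_s:.2f}s")

report = evaluate(handle, split.test, task="binary")
for k in ("accuracy", "sensitivity", "specificity", "auc", "mcc", "kappa"):
    print(f"  test {k}: {report.metrics.values[k]:.4f}")
# On this constructed-separable set every test metric is ~1.0; real
# histology is far harder - this demonstrates the pipeline, not the paper's
# full-scale results.
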