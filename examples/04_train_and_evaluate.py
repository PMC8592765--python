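"""Train a small lesion segmenter end-to-end on synthetic data.

Uses a lightweight pruned-skip UNet++ with a plain encoder so the script
finishes in well under a minute; the full pinned EfficientUNet++ run lives
in dermseg.experiments.learning_sanity.  Prints the per-epoch loss/Dice
curve (the retrospective best epoch is the checkpoint) and the held-out
scores of the restored best weights.
"""

from dermseg import AugmentPolicy, ModelSpec, SyntheticConfig, build_model, generate_samples
from dermseg.training import TrainingConfig, evaluate, train

samples = generate_samples(SyntheticConfig(n_samples=30, size=(64, 64), seed=1))
spec = ModelSpec(
    architecture="unetpp_improved",
    encoder="plain",
    base_width=8,
    decoder_widths=(8, 16, 24, 32, 48),
    dropout_rate=0.0,
)
model = build_model(spec, seed=1)
config = TrainingConfig(epochs=4, batch_size=2, learning_rate=1e-3, seed=1)
result = train(model, samples[:20], samples[20:24], config, AugmentPolicy.disabled())

for r in result.history:
    print(
        f"epoch {r.epoch}: train_loss={r.train_loss:.3f} "
        f"val_loss={r.val_loss:.3f} val_dice={r.val_dice:.3f}"
    )
print(f"best epoch by val_loss: {result.best_epoch}")

model.load_state_dict(result.best_state)
summary = evaluate(model, samples[24:])["summary"]
print(
    "held-out: dice=%.3f iou=%.3f accuracy=%.3f" %
    (summary["dice"], summary["iou"], summary["accuracy"])
)
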