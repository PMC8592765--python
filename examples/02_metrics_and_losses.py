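"""Segmentation metrics and the combined BCE + Dice training loss.

Builds a toy prediction/reference pair, tallies the pixel confusion matrix,
and shows (a) the Dice/IoU/accuracy scores, (b) the exact algebraic link
Dice = 2*IoU/(1+IoU), and (c) how the loss interpolates between BCE and
soft Dice as alpha moves from 0 to 1.
"""

import numpy as np

from dermseg import (
    LossWeights,
    accuracy,
    bce_loss,
    combined_loss,
    confusion_counts,
    dice_loss,
    dice_score,
    iou_score,
)

rng = np.random.default_rng(0)
truth = np.zeros((16, 16), np.uint8)
truth[4:12, 4:12] = 1                      # an 8x8 lesion
pred = np.roll(truth, 2, axis=1)           # prediction shifted 2 px right

c = confusion_counts(pred, truth)
print(f"confusion: tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}")
d, i = dice_score(c), iou_score(c)
print(f"dice={d:.4f}  iou={i:.4f}  accuracy={accuracy(c):.4f}")
print(f"identity 2*iou/(1+iou) = {2 * i / (1 + i):.4f}  (equals dice exactly)")

p = np.clip(pred + rng.normal(0, 0.05, pred.shape), 0.01, 0.99)
for alpha in (0.0, 0.5, 1.0):
    print(
        f"alpha={alpha:3.1f}: combined={combined_loss(p, truth, LossWeights(alpha)):.4f}"
        f"  (bce={bce_loss(p, truth):.4f}, dice_loss={dice_loss(p, truth):.4f})"
    )
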