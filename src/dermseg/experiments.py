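"""Canonical end-to-end experiments on synthetic dermoscopy data.

These are the package's reference sanity experiments, shared by the test
suite and the results-reproduction script:

* :func:`learning_sanity` — train the pinned EfficientUNet++ from random
  init on generated lesion images and score held-out Dice/IoU/accuracy.
  The default problem size (100 train / 20 validation / 40 held-out
  64x64 images, 8 epochs, batch 2) is chosen so the experiment runs in a
  few minutes on one CPU core while leaving a wide margin over the
  Dice >= 0.90 success bar.  From-scratch training uses the learning rate
  of the activation-ablation protocol (1e-3); the 1e-4 default of
  :class:`~dermseg.training.TrainingConfig` is the transfer-learning
  fine-tuning rate.  Dropout is disabled: it exists to counter overfitting
  on scarce real data, which is not at play in a generated-data sanity run.

* :func:`overfit_one_batch` — the classic smoke test: 200 optimisation
  steps on a single fixed batch must drive the combined loss far down.
  It uses an aggressive rate (1e-2), as memorising one batch is a capacity
  check, not a generalisation protocol.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .losses import LossWeights, combined_loss_t
from .models import EFFICIENT_UNETPP, build_model
from .nn.optim import Adam
from .nn.tensor import Tensor
from .preprocess import AugmentPolicy
from .synthetic import SyntheticConfig, generate_samples
from .training import TrainingConfig, evaluate, train, _to_batch

__all__ = ["learning_sanity", "overfit_one_batch"]


def learning_sanity(
    seed: int,
    n_train: int = 100,
    n_val: int = 20,
    n_test: int = 40,
    epochs: int = 8,
    learning_rate: float = 1e-3,
    size: tuple[int, int] = (64, 64),
) -> dict:
    """Train pinned EfficientUNet++ from scratch on synthetic lesions.

    Returns the held-out evaluation summary plus the training history.
    """
    n = n_train + n_val + n_test
    samples = generate_samples(
        SyntheticConfig(n_samples=n, size=size, seed=seed)
    )
    spec = dataclasses.replace(EFFICIENT_UNETPP, dropout_rate=0.0)
    model = build_model(spec, seed=seed)
    config = TrainingConfig(
        learning_rate=learning_rate, batch_size=2, epochs=epochs, seed=seed
    )
    result = train(
        model,
        samples[:n_train],
        samples[n_train : n_train + n_val],
        config,
        AugmentPolicy.disabled(),
    )
    ev = evaluate(model, samples[n_train + n_val :], threshold=config.threshold)
    return {
        "summary": ev["summary"],
        "n_test": ev["n"],
        "history": result.history,
        "best_epoch": result.best_epoch,
    }


def overfit_one_batch(
    seed: int,
    steps: int = 200,
    batch_size: int = 2,
    learning_rate: float = 1e-2,
    size: tuple[int, int] = (64, 64),
) -> list[float]:
    """Drive the combined loss down on one fixed batch; returns the loss trace."""
    samples = generate_samples(
        SyntheticConfig(n_samples=batch_size, size=size, seed=seed)
    )
    spec = dataclasses.replace(EFFICIENT_UNETPP, dropout_rate=0.0)
    model = build_model(spec, seed=seed)
    model.train()
    x, y = _to_batch(samples)
    opt = Adam(model.parameters(), lr=learning_rate)
    weights = LossWeights()
    trace = []
    for _ in range(steps):
        loss = combined_loss_t(model.forward(Tensor(x)).sigmoid(), y, weights)
        trace.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    return trace
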