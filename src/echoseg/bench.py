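"""Shared phantom benchmark harness: train a variant, hold out phantoms,
emit convergence CSVs (test overlap and training loss per iteration block).

This powers both the `bench` CLI subcommand and the acceptance checks: a
tiny model at reduced resolution that trains in minutes on one CPU.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import region_metrics
from .network import NetworkSpec
from .phantom import make_dataset
from .training import TrainConfig, segment_image, train

__all__ = ["tiny_setup", "run_variant", "run_bench"]

TINY_SHAPE = (48, 64)


def tiny_setup(seed=0, n_train=32, n_test=8, channels=16, depth=3):
    """Small-scale phantom split + matching spec/config for CPU runs."""
    n_images = n_train + n_test
    n_patients = max(2, (n_images + 1) // 2)
    images, _ = make_dataset(
        n_patients,
        images_per_patient=2,
        seed=seed,
        size_range=((44, 54), (58, 70)),
        spacing_mean=2.2,  # coarse grid so the anatomy still fits
        spacing_sd=0.15,
    )
    images = images[:n_images]
    trainset, testset = images[:n_train], images[n_train:]
    spec = NetworkSpec(variant="sunet", depth=depth, channels=channels)
    config = TrainConfig(
        learning_rate=3e-3,  # tiny nets tolerate a hotter rate; converges in ~400 iters
        batch_size=8,
        iterations=600,
        frame_shape=TINY_SHAPE,
        train_shape=TINY_SHAPE,
        augment=True,
        seed=seed,
    )
    return trainset, testset, spec, config


def run_variant(variant, trainset, testset, spec, config, record_every=50):
    """Train one variant and measure held-out Dice against true masks."""
    import dataclasses

    spec = dataclasses.replace(spec, variant=variant)
    config = dataclasses.replace(config, record_test_dice_every=record_every)
    result = train(spec, trainset, config, test_images=testset)
    dices = []
    for img in testset:
        mask = segment_image(result.model, img.image, config, spacing=img.spacing)
        dices.append(region_metrics(mask.grid, img.true_mask)[0])
    return result, float(np.mean(dices))


def run_bench(out_dir=None, seed=0, iterations=600, variants=("sunet", "unet"), n_train=32, n_test=8):
    """Run the SU-Net vs U-Net comparison; write Fig-style convergence CSVs.

    Returns {variant: {"mean_test_dice", "loss_trace", "dice_trace"}}.
    """
    import dataclasses

    trainset, testset, spec, config = tiny_setup(seed=seed, n_train=n_train, n_test=n_test)
    config = dataclasses.replace(config, iterations=iterations)
    out = {}
    for variant in variants:
        cfg = config
        if variant == "unet_dc":
            cfg = dataclasses.replace(config, learning_rate=1e-3, batch_size=8)
        result, mean_dice = run_variant(variant, trainset, testset, spec, cfg)
        dice_trace = pd.DataFrame(result.test_dice_trace, columns=["iteration", "mean_test_dice"])
        loss_trace = pd.DataFrame(
            {"iteration": np.arange(1, len(result.loss_trace) + 1), "loss": result.loss_trace}
        )
        out[variant] = {
            "mean_test_dice": mean_dice,
            "loss_trace": loss_trace,
            "dice_trace": dice_trace,
        }
        if out_dir is not None:
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            loss_trace.to_csv(d / f"{variant}_train_loss.csv", index=False)
            dice_trace.to_csv(d / f"{variant}_test_dice.csv", index=False)
    return out
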