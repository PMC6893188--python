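"""U-net ensemble training, learning-rate selection, and prediction.

Five members (by default) are trained on the same labeled tiles with
binary cross-entropy; they differ only by their random seed (weight
initialization and shuffling), seeds ``seed, seed+1, ...``.  At
prediction time the per-pixel sigmoid outputs are averaged arithmetically
across members and thresholded (default 0.5) into the binary
segmentation map; tile maps are reassembled to the parent 960x960 frame
when tiles carry quadrant bookkeeping.

The learning rate is chosen on a held-out 10% validation split: the grid
member with the lowest final-epoch validation cross-entropy wins, ties
going to the smaller rate; rates whose training diverges (non-finite
loss) are excluded with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import imaging, traits
from .nn import Adam
from .unet import UNet, UNetConfig

VALIDATION_FRACTION = 0.10


def _as_batch(arrs) -> np.ndarray:
    x = np.asarray(arrs, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected a stack of 2-D tiles, got shape {x.shape}")
    return x


def _check_masks(masks: np.ndarray) -> np.ndarray:
    m = np.asarray(masks)
    if not np.all(np.isin(np.unique(m), (0, 1))):
        raise ValueError("training masks must be binary (0/1)")
    return m.astype(np.float64)


def train_unet(
    tiles,
    masks,
    config: UNetConfig,
    seed: int | None = None,
    val_tiles=None,
    val_masks=None,
) -> tuple[UNet, dict]:
    """Train a single member; returns (model, history).

    ``history`` holds per-epoch mean training loss and, when a
    validation set is given, per-epoch validation loss.
    """
    x = _as_batch(tiles)
    y = _check_masks(masks)
    if len(x) < 2:
        raise ValueError("need at least 2 labeled tiles")
    seed = config.seed if seed is None else seed
    model = UNet(config, seed=seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(seed + 10_000)
    history = {"train_loss": [], "val_loss": []}
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            sel = order[start : start + config.batch_size]
            losses.append(model.train_step(x[sel], y[sel], opt))
        history["train_loss"].append(float(np.mean(losses)))
        if val_tiles is not None:
            history["val_loss"].append(
                model.loss(_as_batch(val_tiles), _check_masks(val_masks))
            )
    return model, history


def select_learning_rate(
    grid,
    tiles,
    masks,
    config: UNetConfig,
    val_fraction: float = VALIDATION_FRACTION,
) -> tuple[float, dict]:
    """Pick the grid learning rate with the lowest final validation BCE.

    Returns (chosen_rate, report) where ``report`` maps each rate to its
    loss history (``None`` for excluded, diverged rates).
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("learning-rate grid is empty")
    x = _as_batch(tiles)
    y = _check_masks(masks)
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(val_fraction * len(x))))
    order = rng.permutation(len(x))
    val_idx, train_idx = order[:n_val], order[n_val:]

    report, final = {}, {}
    for rate in grid:
        cfg = UNetConfig(**{**asdict(config), "learning_rate": rate})
        _, hist = train_unet(
            x[train_idx], y[train_idx], cfg,
            val_tiles=x[val_idx], val_masks=y[val_idx],
        )
        last = hist["val_loss"][-1]
        if not np.isfinite(last) or not np.all(np.isfinite(hist["train_loss"])):
            warnings.warn(f"learning rate {rate:g} diverged; excluded")
            report[rate] = None
            continue
        report[rate] = hist
        final[rate] = last
    if not final:
        raise RuntimeError("every candidate learning rate diverged")
    best = min(final, key=lambda r: (final[r], r))  # ties -> smaller rate
    return best, report


def train_ensemble(tiles, masks, config: UNetConfig, val_fraction: float = VALIDATION_FRACTION):
    """Train ``config.ensemble_size`` members differing only by seed.

    Returns (members, per-member history).  A common validation split
    (fraction ``val_fraction``, from ``config.seed``) provides the
    per-member validation loss.
    """
    x = _as_batch(tiles)
    y = _check_masks(masks)
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(val_fraction * len(x)))) if val_fraction > 0 else 0
    order = rng.permutation(len(x))
    val_idx, train_idx = order[:n_val], order[n_val:]
    members, histories = [], []
    for k in range(config.ensemble_size):
        model, hist = train_unet(
            x[train_idx], y[train_idx], config, seed=config.seed + k,
            val_tiles=x[val_idx] if n_val else None,
            val_masks=y[val_idx] if n_val else None,
        )
        members.append(model)
        histories.append(hist)
    return members, histories


def ensemble_probability(members, tiles) -> np.ndarray:
    """Arithmetic mean of member sigmoid outputs, per pixel."""
    if not members:
        raise ValueError("need at least one ensemble member")
    x = _as_batch(tiles)
    expect = members[0].config.input_size
    if x.shape[1] != x.shape[2]:
        raise ValueError(f"tiles must be square, got {x.shape[1:]}")
    if x.shape[1] % (2 ** members[0].config.depth) != 0:
        raise ValueError(f"tile size {x.shape[1]} incompatible with network depth")
    del expect  # members are fully convolutional; any pool-compatible size works
    prob = np.zeros(x.shape, dtype=np.float64)
    chunk = 4  # bounds the forward-pass activation caches
    for m in members:
        for lo in range(0, len(x), chunk):
            prob[lo : lo + chunk] += m.predict_proba(x[lo : lo + chunk])
    return prob / len(members)


def predict_ensemble(members, tiles, threshold: float | None = None) -> np.ndarray:
    """Binary segmentation maps for a stack of tiles (prob >= threshold)."""
    threshold = members[0].config.threshold if threshold is None else threshold
    return (ensemble_probability(members, tiles) >= threshold).astype(np.uint8)


def segment_image(members, standardized_image, threshold: float | None = None) -> np.ndarray:
    """Standardized 968x1292 image -> 960x960 binary segmentation map.

    Tiles the image into quadrants, predicts each with the ensemble, and
    reassembles the four tile maps.
    """
    ts = imaging.crop_and_tile(standardized_image)
    maps = predict_ensemble(members, np.stack(ts.tiles), threshold=threshold)
    out = imaging.TileSet(
        tiles=list(maps), parent_id=ts.parent_id,
        crop_offset=ts.crop_offset, quadrants=ts.quadrants,
    )
    return imaging.reassemble(out)


def evaluate_accuracy(predicted: dict, manual: dict) -> dict:
    """Per-trait accuracy (%) of predicted vs manually annotated traits.

    accuracy = 100 * (1 - mean over images of |pred - manual| / manual).
    Images whose manual value is zero (or undefined/NaN) are excluded
    with a warning.  ``predicted``/``manual`` map image id -> value.
    """
    ids = sorted(set(predicted) & set(manual))
    if not ids:
        raise ValueError("no paired records")
    errs = []
    for i in ids:
        m = manual[i]
        if m is None or (isinstance(m, float) and not np.isfinite(m)) or m == 0:
            warnings.warn(f"image {i!r}: manual trait zero/undefined, excluded")
            continue
        errs.append(abs(predicted[i] - m) / m)
    if not errs:
        raise ValueError("all paired records excluded (manual traits zero/undefined)")
    return {"accuracy_pct": 100.0 * (1.0 - float(np.mean(errs))), "n_images": len(errs)}


def pixel_f1(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Pixel-level F1 (Dice) of a binary prediction against truth."""
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(true_mask, dtype=bool)
    tp = float(np.logical_and(p, t).sum())
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * tp / float(denom)


def save_ensemble(members, histories, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, (m, h) in enumerate(zip(members, histories)):
        m.save(directory, name=f"member{k}")
    meta = {
        "config": asdict(members[0].config),
        "seeds": [m.seed for m in members],
        "loss_history": histories,
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))


def load_ensemble(directory):
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    return [UNet.load(directory, name=f"member{k}") for k in range(len(meta["seeds"]))]
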