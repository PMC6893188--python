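"""Synthetic leaf-epidermis images with ground-truth bulliform columns.

Each image shows bright vertical bands (bulliform cell columns, with
sinusoidal edge jitter so edges are not trivially straight) on a darker
background textured like an epidermal cell mosaic (smoothed noise at a
configurable cell scale), plus additive Gaussian pixel noise.

The emitted truth traits are *recomputed from the emitted mask* with the
trait module's own definitions, so mask and truth can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .. import traits


@dataclass
class ImageSimParams:
    """Parameters of one synthetic epidermis image.

    ``column_width_px`` is the nominal width; per-column widths are drawn
    uniformly within +-20% of it (floored at 4 px so ground truth
    survives the run-length > 3 counting rule).  ``column_spacing_jitter``
    is the SD (px) of the horizontal jitter applied to evenly spaced
    column centers.
    """

    height_px: int = 960
    width_px: int = 960
    n_columns: int = 9
    column_width_px: float = 30.0
    column_spacing_jitter: float = 5.0
    background_cell_scale_px: float = 12.0
    column_intensity: float = 0.75
    background_intensity: float = 0.45
    noise_sd: float = 0.08
    edge_jitter_px: float = 2.0
    width_jitter_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_columns < 0:
            raise ValueError("n_columns must be >= 0")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_columns > 0 and self.column_width_px <= traits.MIN_RUN_PX:
            raise ValueError(
                f"column_width_px must exceed {traits.MIN_RUN_PX} px so that "
                "columns survive the run-length counting rule"
            )
        for name in ("column_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _column_layout(params: ImageSimParams, rng: np.random.Generator):
    """Draw per-column (center, width) ensuring no overlap and full containment."""
    n, w = params.n_columns, params.column_width_px
    lo = max(4.0, w * (1 - params.width_jitter_frac))
    hi = w * (1 + params.width_jitter_frac)
    widths = rng.uniform(lo, hi, size=n)
    # Even spacing with jitter; margin keeps columns inside the image.
    spacing = params.width_px / n
    if spacing < hi + 2 * params.edge_jitter_px + 2:
        raise ValueError(
            f"{n} columns of width ~{w:.0f} px do not fit in a "
            f"{params.width_px}-px-wide image without overlap"
        )
    centers = (np.arange(n) + 0.5) * spacing
    centers = centers + rng.normal(0.0, params.column_spacing_jitter, size=n)
    # Clip jittered centers so every column (plus edge jitter) stays inside
    # the image and columns stay disjoint.
    half = widths / 2 + params.edge_jitter_px + 1
    centers = np.clip(centers, np.arange(n) * spacing + half, (np.arange(n) + 1) * spacing - half)
    return centers, widths


def gen_epidermis_image(params: ImageSimParams):
    """Generate one synthetic epidermis image.

    Returns
    -------
    image : float array (height, width) in [0, 1]
    mask : uint8 array, 1 inside a bulliform column
    truth : dict with ``n_columns``, ``width_px`` (NaN when no columns),
        both recomputed from the emitted mask by the trait module.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    mask = np.zeros((h, w), dtype=np.uint8)

    if params.n_columns > 0:
        centers, widths = _column_layout(params, rng)
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        for c, cw in zip(centers, widths):
            # Sinusoidal edge jitter: both edges sway with independent phase.
            wavelength = rng.uniform(150, 400)
            phase_l, phase_r = rng.uniform(0, 2 * np.pi, size=2)
            amp = params.edge_jitter_px
            left = c - cw / 2 + amp * np.sin(2 * np.pi * rows / wavelength + phase_l)
            right = c + cw / 2 + amp * np.sin(2 * np.pi * rows / wavelength + phase_r)
            mask |= ((cols >= left) & (cols < right)).astype(np.uint8)

    # Background: epidermal cell mosaic approximated by band-passed noise.
    texture = gaussian_filter(
        rng.standard_normal((h, w)), sigma=max(params.background_cell_scale_px / 3, 0.5)
    )
    tex_sd = texture.std()
    if tex_sd > 0:
        texture = texture / tex_sd * 0.05
    image = np.where(mask == 1, params.column_intensity, params.background_intensity)
    image = image + texture
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    n_cols = traits.count_columns(mask)
    truth = {"n_columns": n_cols, "width_px": np.nan}
    if n_cols > 0:
        truth["width_px"] = traits.column_width(mask, um_per_px=1.0)
    return image, mask, truth
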