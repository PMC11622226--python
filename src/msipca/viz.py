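"""Hyperspectral renderings of principal-component scores.

Components 1-3 map to red, green and blue as linear min-max gradients
computed globally per component (one colorbar per figure, not per
region); pixels are placed on each region's row-major grid.  Difference
maps render per-pixel score differences as a percent of the reference
component's range, with symmetric signed color limits.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datacube import DatacubeMeta, RegionInfo
from .reference import score_difference_percent

__all__ = ["channel_scale", "rgb_composite", "difference_heatmap", "save_composite_pngs"]


def channel_scale(values: np.ndarray) -> np.ndarray:
    """Min-max scale to 8-bit: (v - min)/(max - min) * 255, round half up.

    A constant (zero-range) channel maps to all zeros.  Invariant to any
    positive affine rescaling of the input.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    scaled = (values - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half up


def _region_grid(reg: RegionInfo, flat: np.ndarray) -> np.ndarray:
    return flat[reg.row_offset : reg.row_offset + reg.n_pixels].reshape(
        reg.height, reg.width
    )


def rgb_composite(
    scores: np.ndarray,
    meta: DatacubeMeta,
    components: Sequence[int] = (1, 2, 3),
) -> dict[str, np.ndarray]:
    """Per-region H x W x 3 uint8 composites of three PCs (1-based numbers).

    Channel scaling is global per component over the whole score set, so a
    pattern keeps the same color across regions.
    """
    scores = np.asarray(scores)
    if len(components) != 3:
        raise ValueError("exactly three components map to R, G, B")
    for c in components:
        if not 1 <= c <= scores.shape[1]:
            raise ValueError(f"component {c} out of range 1..{scores.shape[1]}")
    if scores.shape[0] != meta.n_spectra:
        raise ValueError("scores rows do not match cube spectra")
    channels = [channel_scale(scores[:, c - 1]) for c in components]
    out: dict[str, np.ndarray] = {}
    for reg in meta.regions:
        out[reg.label] = np.dstack([_region_grid(reg, ch) for ch in channels])
    return out


def difference_heatmap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    component: int,
    meta: DatacubeMeta,
) -> tuple[dict[str, np.ndarray], tuple[float, float]]:
    """Per-region signed %-difference maps for one PC plus (min%, max%) limits.

    ``scores_a`` is the reference whose component range normalizes the
    difference; signs must be aligned beforehand.
    """
    pct, limits = score_difference_percent(scores_a, scores_b, component)
    maps = {reg.label: _region_grid(reg, pct) for reg in meta.regions}
    return maps, limits


def save_composite_pngs(
    composites: Mapping[str, np.ndarray], out_dir: str | os.PathLike, stem: str = "pc_rgb"
) -> list[Path]:
    """Write one PNG per region composite."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, img in composites.items():
        p = out_dir / f"{stem}_{label}.png"
        Image.fromarray(img, mode="RGB").save(p)
        paths.append(p)
    return paths


def save_heatmap_png(
    heatmap: np.ndarray,
    limits: tuple[float, float],
    path: str | os.PathLike,
    title: str | None = None,
) -> Path:
    """Render one signed heatmap with a colorbar annotated with the limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(abs(limits[0]), abs(limits[1])) or 1e-12
    fig, ax = plt.subplots()
    im = ax.imshow(heatmap, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("difference (% of reference PC range)")
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
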