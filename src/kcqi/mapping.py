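"""Pixel-wise quality-index prediction on corrected cubes and pseudocolor maps.

A trained spectra->KCQI model is applied to every fruit-mask pixel of a
radiometrically corrected cube (restricted to the model's band subset); the
background stays masked.  Rendering uses a colour scale shared across a day
series so temporal drift is visually comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hsi import HyperCube, fruit_mask

__all__ = ["KCQIMap", "predict_map", "render_map"]


@dataclass
class KCQIMap:
    """Per-pixel index values (NaN off-mask), the fruit mask and colour scale."""

    values: np.ndarray
    mask: np.ndarray
    vmin: float
    vmax: float
    cmap: str = "jet"

    def mean(self) -> float:
        return float(np.nanmean(self.values[self.mask])) if self.mask.any() else np.nan


def predict_map(
    cube: HyperCube,
    model,
    band_indices,
    mask: np.ndarray | None = None,
    color_scale: tuple[float, float] | None = None,
) -> KCQIMap:
    """Apply ``model`` to every fruit pixel of a corrected cube.

    ``band_indices`` must be the subset the model was trained on; the model
    carries its own calibration standardization, so pixels receive exactly
    the train-time transform.
    """
    if cube.kind != "corrected":
        raise ValueError("predict_map requires a radiometrically corrected cube")
    idx = np.asarray(band_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty band subset")
    if idx.min() < 0 or idx.max() >= cube.axis.n_bands:
        raise ValueError(
            f"band indices outside cube axis [0, {cube.axis.n_bands})"
        )
    if mask is None:
        mask = fruit_mask(cube)
    h, w, _ = cube.shape
    values = np.full((h, w), np.nan)
    if mask.any():
        spectra = np.asarray(cube.data, dtype=float)[mask][:, idx]
        values[mask] = model.predict(spectra)
    else:
        warnings.warn("empty fruit mask; map contains no values", stacklevel=2)
    if color_scale is None:
        finite = values[np.isfinite(values)]
        if finite.size:
            vmin, vmax = float(finite.min()), float(finite.max())
            if vmin == vmax:
                vmin, vmax = vmin - 0.5, vmax + 0.5
        else:
            vmin, vmax = 0.0, 1.0
    else:
        vmin, vmax = color_scale
        if not vmin < vmax:
            raise ValueError("color scale requires vmin < vmax")
    return KCQIMap(values=values, mask=mask, vmin=vmin, vmax=vmax)


def render_map(kmap: KCQIMap, path, title: str | None = None) -> None:
    """Write a PNG pseudocolor rendering with a colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not kmap.mask.any():
        warnings.warn("rendering an all-masked map (background only)",
                      stacklevel=2)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    shown = np.ma.masked_invalid(kmap.values)
    im = ax.imshow(shown, cmap=kmap.cmap, vmin=kmap.vmin, vmax=kmap.vmax)
    ax.set_facecolor("black")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="KCQI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
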