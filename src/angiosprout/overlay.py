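"""QC visualisation: mask export and overlay images.

Masks export as 8-bit TIFF (0/255).  The overlay PNG shows the guides in
red, the ECM gel in green and the reference line as a red dotted line over
the nuclear image, mirroring the assay's published QC figures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .chip_geometry import ChipMasks


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def overlay_rgb(nuclear_image: np.ndarray, masks: ChipMasks) -> np.ndarray:
    """8-bit RGB QC overlay (guides red, gel green, dotted reference line)."""
    img = np.asarray(nuclear_image, dtype=np.float64)
    lo, hi = np.percentile(img, (1, 99.5))
    base = np.clip((img - lo) / max(hi - lo, 1e-12), 0, 1)
    rgb = np.stack([base] * 3, axis=-1)

    guides = masks.top_guide | masks.bottom_guide
    rgb[guides] = 0.6 * rgb[guides] + 0.4 * np.array([1.0, 0.0, 0.0])
    rgb[masks.ecm_mask] = 0.7 * rgb[masks.ecm_mask] + 0.3 * np.array([0.0, 1.0, 0.0])

    y = masks.reference_y_px
    if 0 <= y < rgb.shape[0]:
        xs = np.arange(rgb.shape[1])
        dotted = xs[(xs // 4) % 2 == 0]  # 4-px dashes
        rgb[y, dotted] = [1.0, 0.0, 0.0]
    return (rgb * 255).astype(np.uint8)


def write_overlay_png(
    nuclear_image: np.ndarray, masks: ChipMasks, path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = overlay_rgb(nuclear_image, masks)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb)
    ax.set_axis_off()
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
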