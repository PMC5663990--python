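"""Dose-map figure export: orthogonal montage with a dose color bar."""

from __future__ import annotations

import numpy as np


def save_dose_montage(dose_map: np.ndarray, spacing, path, title: str | None = None):
    """Axial / sagittal / coronal mid-slices of a dose volume as one PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dose = np.asarray(dose_map, dtype=float)
    sx, sy, sz = spacing
    vmax = max(float(np.nanmax(dose)), 1e-9)
    slices = [
        (dose[:, :, dose.shape[2] // 2].T, (sx, sy), "axial"),
        (dose[dose.shape[0] // 2, :, :].T, (sy, sz), "sagittal"),
        (dose[:, dose.shape[1] // 2, :].T, (sx, sz), "coronal"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (img, (su, sv), name) in zip(axes, slices):
        im = ax.imshow(
            img,
            origin="lower",
            cmap="inferno",
            vmin=0.0,
            vmax=vmax,
            aspect=sv / su,
            interpolation="nearest",
        )
        ax.set_title(name)
        ax.axis("off")
    cbar = fig.colorbar(im, ax=axes, fraction=0.03, pad=0.02)
    cbar.set_label("dose [Gy]")
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
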