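"""Figure generation: Σ/R heatmaps and covariance-diagonal overlays."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dataset import WavelengthAxis  # noqa: E402

__all__ = ["render_heatmap", "render_diagonals"]


def render_heatmap(M, axis: WavelengthAxis, kind: str = "covariance", path=None):
    """Wavelength-labeled heatmap of a p×p error covariance or correlation.

    Correlation maps use a fixed [−1, 1] color scale so structure is
    comparable across figures; covariance maps use a data-driven scale (their
    magnitude is the message).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (axis.p, axis.p):
        raise ValueError(
            f"matrix shape {M.shape} does not match axis length {axis.p}"
        )
    if kind not in ("covariance", "correlation"):
        raise ValueError(f"kind must be 'covariance' or 'correlation', got {kind!r}")
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    extent = [axis.values[0], axis.values[-1], axis.values[-1], axis.values[0]]
    kwargs = dict(vmin=-1, vmax=1, cmap="RdBu_r") if kind == "correlation" else {}
    im = ax.imshow(M, extent=extent, aspect="auto", **kwargs)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("wavelength (nm)")
    ax.set_title(f"error {kind} matrix")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig


def render_diagonals(diagonals: dict, axis: WavelengthAxis, path=None):
    """Overlay labeled Σ diagonals (error variance vs wavelength).

    ``diagonals`` maps a label (session or background-mode tag) to a p-vector.
    """
    if not diagonals:
        raise ValueError("no diagonals to plot")
    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    for label, diag in diagonals.items():
        diag = np.asarray(diag, dtype=float)
        if diag.size != axis.p:
            raise ValueError(
                f"diagonal {label!r} has length {diag.size}, expected {axis.p}"
            )
        ax.plot(axis.values, diag, label=str(label), lw=1.2)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("error variance (%R)$^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
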