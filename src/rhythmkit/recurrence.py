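"""Recurrence matrices of IOI sequences.

The recurrence matrix of a sequence of IOIs holds the absolute difference
between every IOI and every other: M[i, j] = |IOI_i - IOI_j|, with both axes
indexing the IOIs in sequential order.  Rendered as an image (white = no
difference, darker = larger), it exposes higher-order temporal structure —
an isochronous sequence is an almost-white plot, a block of similar IOIs
followed by an alternating pattern shows as block structure — that scalar
indices cannot.

The color scale is per-plot by default (min–max of the plotted matrix), so
the same shade does not mean the same absolute difference across plots; a
shared ``vmax`` can be passed for cross-plot comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = ["RecurrenceMatrix", "recurrence_matrix", "render_recurrence"]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Symmetric, zero-diagonal matrix of absolute pairwise IOI differences."""

    values: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("recurrence matrix must be square")
        if np.any(v < 0) or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValidationError(
                "recurrence matrix must be non-negative, symmetric, zero-diagonal"
            )

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def recurrence_matrix(iois, *, sequence_id: str = "") -> RecurrenceMatrix:
    """All-pairs absolute IOI differences: M[i, j] = |IOI_i - IOI_j|."""
    x = np.asarray(iois, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError("recurrence matrix needs >= 2 IOIs")
    return RecurrenceMatrix(
        values=np.abs(x[:, None] - x[None, :]), sequence_id=sequence_id
    )


def render_recurrence(
    matrix: RecurrenceMatrix,
    path: str | Path,
    *,
    vmax: float | None = None,
    cmap: str = "Greys",
    dpi: int = 150,
) -> Path:
    """Render the matrix as a raster image; returns the written path.

    White encodes zero difference and darker shades larger ones (grayscale by
    default).  ``vmax`` fixes the top of the scale for comparison across
    plots; without it the scale is per-plot and the legend caveat notes that
    equal shades are not comparable between figures.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    per_plot = vmax is None
    if per_plot:
        vmax = float(matrix.values.max())
        if vmax == 0:
            vmax = 1.0  # all-zero matrix renders uniformly white
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        matrix.values, cmap=cmap, vmin=0.0, vmax=vmax, origin="lower",
        interpolation="nearest",
    )
    ax.set_xlabel("IOI index")
    ax.set_ylabel("IOI index")
    title = f"Recurrence plot {matrix.sequence_id}".strip()
    ax.set_title(title)
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("|IOI difference| (s)")
    if per_plot:
        fig.text(
            0.01, 0.01,
            "color scale is per-plot: equal shades are not comparable across plots",
            fontsize=6,
        )
    try:
        fig.savefig(path, dpi=dpi)
    except OSError as exc:
        raise IOError(f"cannot write recurrence plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path
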