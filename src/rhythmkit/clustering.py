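"""Hierarchical clustering of per-sequence beat frequencies within individuals.

Individuals often favour a narrow band of tempi; clustering the exact beat
frequencies of an individual's sequences makes such preferences visible and
quantifiable.  Frequencies are clustered agglomeratively with group-average
(UPGMA) linkage on Euclidean (1-D absolute) distances and the tree is cut at
a dissimilarity threshold (default 0.05, applied to the raw Hz distances —
a deliberately tight literal cut; ``normalize=True`` divides frequencies by
their mean first so the threshold acts on relative tempo differences).  The
share of sequences in the largest cluster summarizes how concentrated an
individual's beat production is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError
from .sequence_io import Dataset

logger = logging.getLogger("rhythmkit")

__all__ = ["ClusterResult", "cluster_beats", "cluster_report"]

DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class ClusterResult:
    """Partition of beat frequencies with the largest-cluster share."""

    labels: np.ndarray
    largest_share: float
    n_clusters: int
    threshold: float
    method_tag: str = ""
    largest_center: float = float("nan")
    largest_range: tuple[float, float] = (float("nan"), float("nan"))


def cluster_beats(
    freqs,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    normalize: bool = False,
    method_tag: str = "",
) -> ClusterResult:
    """UPGMA clustering of 1-D beat frequencies cut at ``threshold``.

    The cut uses the "distance" criterion: two frequencies share a cluster
    iff they merge at cophenetic distance <= threshold.  A single input
    frequency forms one trivial cluster (with a warning).
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValidationError("cluster_beats needs a 1-D array of frequencies")
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if f.size == 1:
        logger.warning("single frequency: trivial one-point cluster")
        return ClusterResult(
            labels=np.array([1]),
            largest_share=1.0,
            n_clusters=1,
            threshold=threshold,
            method_tag=method_tag,
            largest_center=float(f[0]),
            largest_range=(float(f[0]), float(f[0])),
        )
    x = f / f.mean() if normalize else f
    Z = linkage(x[:, None], method="average", metric="euclidean")
    labels = fcluster(Z, t=threshold, criterion="distance")
    counts = np.bincount(labels)[1:]
    biggest = int(np.argmax(counts)) + 1
    members = f[labels == biggest]
    return ClusterResult(
        labels=labels,
        largest_share=float(counts.max() / f.size),
        n_clusters=int(counts.size),
        threshold=threshold,
        method_tag=method_tag,
        largest_center=float(members.mean()),
        largest_range=(float(members.min()), float(members.max())),
    )


def cluster_report(
    beats_by_method: dict[str, dict[str, list[float]]],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    normalize: bool = False,
    plot_path=None,
):
    """Per-individual largest-cluster table across beat-detection methods.

    ``beats_by_method`` maps method tag -> individual id -> per-sequence beat
    frequencies (Hz).  Individuals with fewer than 2 sequences are excluded
    with a warning.  Returns a pandas DataFrame with columns (individual,
    method, n_sequences, largest_share, n_clusters, center_hz, low_hz,
    high_hz); if ``plot_path`` is given, a dot plot with the largest cluster
    highlighted is written there.
    """
    import pandas as pd

    rows = []
    for method, per_ind in beats_by_method.items():
        for ind, freqs in per_ind.items():
            if len(freqs) < 2:
                logger.warning(
                    "individual %r has < 2 sequences for method %s; excluded",
                    ind, method,
                )
                continue
            res = cluster_beats(
                freqs, threshold, normalize=normalize, method_tag=method
            )
            rows.append(
                dict(
                    individual=ind,
                    method=method,
                    n_sequences=len(freqs),
                    largest_share=res.largest_share,
                    n_clusters=res.n_clusters,
                    center_hz=res.largest_center,
                    low_hz=res.largest_range[0],
                    high_hz=res.largest_range[1],
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "individual", "method", "n_sequences", "largest_share",
            "n_clusters", "center_hz", "low_hz", "high_hz",
        ],
    )
    if plot_path is not None:
        _plot_clusters(beats_by_method, threshold, normalize, plot_path)
    return table


def _plot_clusters(beats_by_method, threshold, normalize, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    methods = list(beats_by_method)
    fig, axes = plt.subplots(
        len(methods), 1, figsize=(7, 2.6 * len(methods)), squeeze=False
    )
    for ax, method in zip(axes[:, 0], methods):
        per_ind = {k: v for k, v in beats_by_method[method].items() if len(v) >= 2}
        for i, (ind, freqs) in enumerate(sorted(per_ind.items())):
            res = cluster_beats(freqs, threshold, normalize=normalize)
            f = np.asarray(freqs, dtype=float)
            in_big = res.labels == (np.argmax(np.bincount(res.labels)[1:]) + 1)
            x = np.full(f.size, i)
            ax.plot(x[~in_big], f[~in_big], "o", color="0.6", ms=4)
            ax.plot(x[in_big], f[in_big], "o", color="crimson", ms=4)
            ax.annotate(
                f"{res.largest_share * 100:.0f}%",
                (i, ax.get_ylim()[0]),
                xytext=(0, -18), textcoords="offset points",
                ha="center", fontsize=7,
            )
        ax.set_xticks(range(len(per_ind)))
        ax.set_xticklabels(sorted(per_ind), fontsize=7)
        ax.set_ylabel("beat (Hz)")
        ax.set_title(method, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
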