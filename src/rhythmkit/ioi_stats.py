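"""IOI-level descriptive statistics: coefficient of variation, nPVI, beat
conversion and dataset summaries.

The coefficient of variation (CV) of a set of IOIs is the ratio of their
sample standard deviation to their mean, a scale-free index of how spread
the intervals are.  The plain estimator underestimates the population CV for
small n, so the small-sample correction

    CV* = (1 + 1/(4n)) * CV

is reported alongside it and used for all summaries.

The normalized Pairwise Variability Index (nPVI) compares *adjacent* IOIs:
each neighbouring pair contributes |a-b| divided by the pair mean, and the
average contribution times 100 is the index.  It is 0 for a perfectly
isochronous sequence and approaches 200 for alternating extreme ratios.

A mean IOI converts to an "exact beat frequency" by taking its reciprocal
(Hz = 1/s): a sequence whose intervals average 0.1 s is described by a
10 Hz beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .sequence_io import Dataset

__all__ = [
    "CVResult",
    "DatasetSummary",
    "coefficient_of_variation",
    "npvi",
    "beat_from_mean_ioi",
    "dataset_summary",
]


@dataclass(frozen=True)
class CVResult:
    """Plain (cv_hat) and small-sample-corrected (cv_star) coefficient of variation."""

    cv_hat: float
    cv_star: float
    n: int
    mean: float
    sd: float


def coefficient_of_variation(iois) -> CVResult:
    """CV of a set of IOIs with its unbiased small-sample correction.

    The standard deviation uses the (n-1) denominator, which the correction
    factor (1 + 1/(4n)) presupposes.  Requires n >= 2 strictly positive IOIs.
    """
    x = np.asarray(iois, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"CV needs >= 2 IOIs, got {n}")
    if np.any(x <= 0):
        raise InsufficientDataError("CV of IOIs requires strictly positive values")
    mean = float(x.mean())
    # exactly-constant input must score exactly zero (float cancellation in
    # the two-pass variance otherwise leaves ~1e-17 residue)
    sd = 0.0 if np.all(x == x[0]) else float(x.std(ddof=1))
    cv_hat = sd / mean
    cv_star = (1.0 + 1.0 / (4.0 * n)) * cv_hat
    return CVResult(cv_hat=cv_hat, cv_star=cv_star, n=n, mean=mean, sd=sd)


def npvi(iois) -> float:
    """Normalized Pairwise Variability Index of a sequence of IOIs.

    nPVI = 100/(m-1) * sum_k |IOI_k - IOI_{k+1}| / ((IOI_k + IOI_{k+1})/2)

    for m IOIs.  Zero iff every adjacent pair is equal; always < 200 for
    positive IOIs.
    """
    x = np.asarray(iois, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"nPVI needs >= 2 IOIs, got {x.size}")
    a, b = x[:-1], x[1:]
    return float(np.mean(np.abs(a - b) / ((a + b) / 2.0)) * 100.0)


def beat_from_mean_ioi(iois) -> float:
    """Exact beat frequency (Hz) implied by the mean IOI: 1 / mean(IOI)."""
    x = np.asarray(iois, dtype=float)
    if x.size < 1:
        raise InsufficientDataError("beat_from_mean_ioi needs >= 1 IOI")
    if np.any(x <= 0):
        raise InsufficientDataError("IOIs must be strictly positive")
    return float(1.0 / x.mean())


@dataclass(frozen=True)
class DatasetSummary:
    """Per-dataset IOI summary mirroring a standard species-level results row.

    ``cv_overall`` is CV* of all IOIs pooled; ``cv_sequence_mean`` is the mean
    of per-sequence CV*.  Their difference indicates variation between
    sequences (and hence possibly between individuals): internally consistent
    but mutually different sequences yield a small per-sequence CV and a large
    pooled CV.  ``npvi_overall`` concatenates all sequences but skips the
    adjacent pair straddling each sequence boundary, because those two IOIs
    are not adjacent in time (recorded in ``boundary_pairs_excluded``).
    """

    name: str
    mean_ioi: float
    sd_ioi: float
    cv_overall: float
    cv_sequence_mean: float
    ioi_range: tuple[float, float]
    n_iois: int
    n_sequences: int
    npvi_per_sequence: tuple[float, ...]
    npvi_mean: float
    npvi_overall: float
    cv_gap: float
    sequence_durations: tuple[float, ...]
    boundary_pairs_excluded: int
    skipped_sequences: tuple[str, ...] = field(default=())


def dataset_summary(ds: Dataset, *, name: str | None = None) -> DatasetSummary:
    """Summarize a dataset's IOIs at the pooled and per-sequence level.

    Sequences with fewer than 2 IOIs cannot contribute a CV or nPVI; they are
    skipped with a warning and listed in ``skipped_sequences`` (their IOIs
    still count toward the pooled statistics).
    """
    import logging

    seqs = ds.ioi_sequences()
    if not seqs:
        raise InsufficientDataError(f"dataset {ds.name!r} has no sequences")

    usable = [s for s in seqs if len(s) >= 2]
    skipped = tuple(s.sequence_id for s in seqs if len(s) < 2)
    if skipped:
        logging.getLogger("rhythmkit").warning(
            "dataset %r: skipped %d sequence(s) with < 2 IOIs: %s",
            ds.name, len(skipped), list(skipped),
        )
    if not usable:
        raise InsufficientDataError(
            f"dataset {ds.name!r}: no sequence has >= 2 IOIs"
        )

    pooled = np.concatenate([s.iois for s in seqs])
    cv_pooled = coefficient_of_variation(pooled)
    per_seq_cv = [coefficient_of_variation(s.iois).cv_star for s in usable]
    per_seq_npvi = tuple(npvi(s.iois) for s in usable)

    # overall nPVI: pairs within sequences only, averaged across the dataset
    contribs = []
    for s in usable:
        a, b = s.iois[:-1], s.iois[1:]
        contribs.append(np.abs(a - b) / ((a + b) / 2.0) * 100.0)
    all_contribs = np.concatenate(contribs)
    boundary_excluded = len(usable) - 1

    cv_overall = cv_pooled.cv_star
    cv_sequence_mean = float(np.mean(per_seq_cv))
    return DatasetSummary(
        name=name if name is not None else ds.name,
        mean_ioi=cv_pooled.mean,
        sd_ioi=cv_pooled.sd,
        cv_overall=cv_overall,
        cv_sequence_mean=cv_sequence_mean,
        ioi_range=(float(pooled.min()), float(pooled.max())),
        n_iois=int(pooled.size),
        n_sequences=len(seqs),
        npvi_per_sequence=per_seq_npvi,
        npvi_mean=float(np.mean(per_seq_npvi)),
        npvi_overall=float(all_contribs.mean()),
        cv_gap=cv_overall - cv_sequence_mean,
        sequence_durations=tuple(float(s.iois.sum()) for s in seqs),
        boundary_pairs_excluded=boundary_excluded,
        skipped_sequences=skipped,
    )
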