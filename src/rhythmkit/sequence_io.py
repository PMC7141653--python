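"""Sequence containers and I/O for element-onset label files and IOI tables.

The analysis primitive throughout the package is the element onset: the time
(in seconds) at which a syllable, call or click begins.  An
:class:`ElementSequence` holds the onsets of one vocalization or click train;
an :class:`IOISequence` holds the inter-onset intervals (IOIs) derived from
it, i.e. ``onsets[i+1] - onsets[i]``.  A :class:`Dataset` groups sequences,
typically one dataset per species with sequences attributed to individuals.

Two on-disk formats are supported:

* tab-separated label files (one per sequence) with an onset and offset
  column per element, as exported by common labelling software;
* long-format IOI tables (CSV/TSV/XLSX) with one IOI per row and columns for
  species, individual, sequence id and the IOI in seconds.

All times are seconds internally; the readers accept ``unit="ms"`` to convert
on ingest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("rhythmkit")

__all__ = [
    "ElementSequence",
    "IOISequence",
    "Dataset",
    "read_label_file",
    "read_ioi_table",
    "write_ioi_table",
    "compute_iois",
    "onsets_from_iois",
]

_UNIT_SCALE = {"s": 1.0, "ms": 1e-3}


@dataclass(frozen=True)
class ElementSequence:
    """Onsets (and optionally offsets/labels) of one acoustic sequence.

    Invariants: onsets are strictly increasing; if offsets are present they
    have the same length and ``offsets[i] > onsets[i]``.
    """

    onsets: np.ndarray
    sequence_id: str = ""
    individual_id: str = ""
    species: str = ""
    offsets: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.ndim != 1 or onsets.size < 1:
            raise ValidationError("onsets must be a non-empty 1-D array")
        if not np.all(np.isfinite(onsets)):
            raise ValidationError("onsets must be finite")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("onsets must be strictly increasing")
        if self.offsets is not None:
            offsets = np.asarray(self.offsets, dtype=float)
            object.__setattr__(self, "offsets", offsets)
            if offsets.shape != onsets.shape:
                raise ValidationError("offsets must match onsets in length")
            if not np.all(offsets > onsets):
                raise ValidationError("each offset must exceed its onset")
        if self.labels is not None and len(self.labels) != onsets.size:
            raise ValidationError("labels must match onsets in length")

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def duration(self) -> float:
        """Time from first to last onset, seconds."""
        return float(self.onsets[-1] - self.onsets[0])


@dataclass(frozen=True)
class IOISequence:
    """Strictly positive inter-onset intervals of one sequence, seconds."""

    iois: np.ndarray
    sequence_id: str = ""
    individual_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        iois = np.asarray(self.iois, dtype=float)
        object.__setattr__(self, "iois", iois)
        if iois.ndim != 1:
            raise ValidationError("iois must be 1-D")
        if not np.all(np.isfinite(iois)):
            raise ValidationError("iois must be finite")
        if np.any(iois <= 0):
            raise ValidationError("all IOIs must be strictly positive")

    def __len__(self) -> int:
        return int(self.iois.size)

    @property
    def duration(self) -> float:
        """Span of the reconstructed onset sequence, seconds."""
        return float(self.iois.sum())


@dataclass
class Dataset:
    """A named collection of sequences, grouped by individual."""

    name: str = ""
    sequences: list[IOISequence | ElementSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sequence_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sequence_ids in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def ioi_sequences(self) -> list[IOISequence]:
        """All sequences as IOI sequences, deriving IOIs where needed."""
        return [
            s if isinstance(s, IOISequence) else compute_iois(s)
            for s in self.sequences
        ]

    def by_individual(self) -> dict[str, list[IOISequence | ElementSequence]]:
        groups: dict[str, list] = {}
        for s in self.sequences:
            groups.setdefault(s.individual_id, []).append(s)
        return groups

    def pooled_iois(self) -> np.ndarray:
        """All IOIs of the dataset concatenated (sequence boundaries lost)."""
        seqs = self.ioi_sequences()
        if not seqs:
            return np.empty(0)
        return np.concatenate([s.iois for s in seqs])


def compute_iois(seq: ElementSequence) -> IOISequence:
    """Inter-onset intervals of *seq*: ``iois[i] = onsets[i+1] - onsets[i]``."""
    if len(seq) < 2:
        raise InsufficientDataError(
            f"sequence {seq.sequence_id!r}: need >= 2 onsets to form IOIs, got {len(seq)}"
        )
    return IOISequence(
        iois=np.diff(seq.onsets),
        sequence_id=seq.sequence_id,
        individual_id=seq.individual_id,
        species=seq.species,
    )


def onsets_from_iois(iois: IOISequence | Sequence[float]) -> ElementSequence:
    """Reconstruct onsets from IOIs by cumulative summation, first onset at 0.

    The absolute start time of the original recording is unrecoverable from
    IOIs, but every statistic in this package is translation-invariant, so
    anchoring at t=0 loses nothing.  An empty IOI list yields the degenerate
    single-onset sequence at t=0 (with a warning).
    """
    if isinstance(iois, IOISequence):
        values = iois.iois
        meta = dict(
            sequence_id=iois.sequence_id,
            individual_id=iois.individual_id,
            species=iois.species,
        )
    else:
        values = np.asarray(iois, dtype=float)
        meta = {}
    if values.size == 0:
        warnings.warn("empty IOI list: returning a single onset at t=0", stacklevel=2)
        return ElementSequence(onsets=np.zeros(1), **meta)
    onsets = np.concatenate([[0.0], np.cumsum(values)])
    return ElementSequence(onsets=onsets, **meta)


def read_label_file(
    path: str | Path,
    *,
    strict: bool = False,
    unit: str = "s",
    sequence_id: str | None = None,
    individual_id: str = "",
    species: str = "",
) -> ElementSequence:
    """Read a tab-separated onset/offset label file into an ElementSequence.

    Expected layout: ``onset<TAB>offset[<TAB>label]`` per element, header row
    optional.  Rows out of time order are sorted with a warning by default
    (field label files are frequently hand-edited); ``strict=True`` raises
    instead.  An offset smaller than its onset is always an error, reported
    with its 1-based row number.
    """
    path = Path(path)
    scale = _unit_scale(unit)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read label file {path}: {exc}") from exc

    onsets: list[float] = []
    offsets: list[float] = []
    labels: list[str] = []
    have_label = False
    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path} row {lineno}: expected onset and offset columns")
        try:
            on, off = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not onsets:
                continue  # header row
            raise ParseError(
                f"{path} row {lineno}: non-numeric onset/offset {parts[:2]!r}"
            ) from None
        if off <= on:
            raise ParseError(f"{path} row {lineno}: offset {off} <= onset {on}")
        onsets.append(on * scale)
        offsets.append(off * scale)
        if len(parts) > 2:
            have_label = True
            labels.append(parts[2])
        else:
            labels.append("")

    if not onsets:
        raise ParseError(f"{path}: no element rows found")

    order = np.argsort(onsets, kind="stable")
    if not np.array_equal(order, np.arange(len(onsets))):
        if strict:
            raise ParseError(f"{path}: rows are not in ascending onset order")
        logger.warning("%s: rows out of time order; sorted by onset", path)
    onsets_a = np.asarray(onsets)[order]
    offsets_a = np.asarray(offsets)[order]
    labels_t = tuple(np.asarray(labels, dtype=object)[order]) if have_label else None
    return ElementSequence(
        onsets=onsets_a,
        offsets=offsets_a,
        labels=labels_t,
        sequence_id=sequence_id if sequence_id is not None else path.stem,
        individual_id=individual_id,
        species=species,
    )


DEFAULT_COLUMNS: Mapping[str, str] = {
    "species": "species",
    "individual": "individual",
    "sequence": "sequence_id",
    "ioi": "ioi_s",
}


def read_ioi_table(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    unit: str = "s",
    name: str | None = None,
    sheet: int | str = 0,
) -> Dataset:
    """Read a long-format IOI table (CSV/TSV/XLSX) into a Dataset.

    ``columns`` maps the roles ``species``/``individual``/``sequence``/``ioi``
    to the actual column names of the file; the defaults match the tables
    this package writes.  IOIs must be strictly positive; offending rows are
    listed in the error.  Rows are grouped into one IOISequence per sequence
    id, in file order.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    scale = _unit_scale(unit)

    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    elif suffix in {".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")

    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; available: {list(df.columns)}"
        )

    ioi_col = colmap["ioi"]
    iois = pd.to_numeric(df[ioi_col], errors="coerce")
    bad = df.index[~(iois > 0) | iois.isna()]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive or non-numeric IOI in rows {list(bad[:20])}"
            + (" ..." if len(bad) > 20 else "")
        )

    sequences: list[IOISequence] = []
    for seq_id, grp in df.groupby(colmap["sequence"], sort=False):
        sequences.append(
            IOISequence(
                iois=pd.to_numeric(grp[ioi_col]).to_numpy() * scale,
                sequence_id=str(seq_id),
                individual_id=str(grp[colmap["individual"]].iloc[0]),
                species=str(grp[colmap["species"]].iloc[0]),
            )
        )
    return Dataset(name=name if name is not None else path.stem, sequences=sequences)


def write_ioi_table(ds: Dataset, path: str | Path) -> pd.DataFrame:
    """Write a dataset as normalized long-format CSV; returns the frame.

    Columns: species, individual, sequence_id, ioi_index, ioi_s.  Values are
    written at full float precision so a read/write round trip preserves the
    IOIs exactly.
    """
    rows = []
    for seq in ds.ioi_sequences():
        for i, v in enumerate(seq.iois):
            rows.append(
                dict(
                    species=seq.species,
                    individual=seq.individual_id,
                    sequence_id=seq.sequence_id,
                    ioi_index=i,
                    ioi_s=v,
                )
            )
    df = pd.DataFrame(
        rows, columns=["species", "individual", "sequence_id", "ioi_index", "ioi_s"]
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def _unit_scale(unit: str) -> float:
    try:
        return _UNIT_SCALE[unit]
    except KeyError:
        raise ValidationError(f"unknown time unit {unit!r}; use 's' or 'ms'") from None
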