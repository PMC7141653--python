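"""Generate-and-test (GAT) search for the best-fitting isochronous beat.

Every candidate frequency f on a grid (default 2–100 Hz in 0.01 Hz steps)
defines a perfectly isochronous beat grid {t0 + k/f} anchored at the first
observed onset t0.  Each onset's deviation is its distance to the nearest
beat (at most half a period); the root-mean-square of these deviations is
the RMSD in seconds.  Expressed as a fraction of the beat period,

    FRMSD = RMSD * f,

the score becomes comparable across frequencies, and minimizing it favours
the slowest beat among harmonically equivalent fits: if every onset sits on
the grid of f it also sits on the grid of every integer multiple of f with
identical RMSD = 0, but a tie broken toward the lowest frequency returns the
fundamental.

The grid is generated index-based (f_min + k*df) to avoid cumulative
floating-step drift, with both endpoints included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = ["GATResult", "beat_rmsd", "gat_search"]

DEFAULT_F_MIN = 2.0
DEFAULT_F_MAX = 100.0
DEFAULT_DF = 0.01
MAX_GRID_POINTS = 2_000_000


@dataclass(frozen=True)
class GATResult:
    """FRMSD curve over the candidate-frequency grid and its best beat."""

    grid: np.ndarray
    frmsd_curve: np.ndarray
    best_frequency: float
    best_frmsd: float
    rmsd_at_best: float
    convention: str = "rmsd_times_f"


def _deviations(rel_onsets: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Distance of each onset to its nearest beat, shape (len(f), len(onsets)).

    rel_onsets are onsets minus the anchor t0 (the first onset).
    """
    period = 1.0 / f[:, None]
    phase = np.mod(rel_onsets[None, :], period)
    return np.minimum(phase, period - phase)


def beat_rmsd(
    onsets,
    f: float,
    *,
    convention: str = "rmsd_times_f",
    optimize_phase: bool = False,
) -> tuple[float, float]:
    """(RMSD, FRMSD) of the onsets against the isochronous beat of frequency f.

    The beat grid is anchored at the first onset by default;
    ``optimize_phase=True`` instead minimizes the RMSD over the grid phase
    (the circular-mean phase of the onsets).  ``convention`` selects the
    frequency normalization: ``"rmsd_times_f"`` (deviation as a fraction of
    the cycle; the default) or ``"rmsd_over_f"`` (the literal division by
    frequency).
    """
    t = _check_onsets(onsets)
    if f <= 0:
        raise ValidationError("beat frequency must be positive")
    rel = t - t[0]
    if optimize_phase:
        rmsd = _phase_optimal_rmsd(rel, float(f))
    else:
        dev = _deviations(rel, np.asarray([float(f)]))[0]
        rmsd = float(np.sqrt(np.mean(dev**2)))
    return rmsd, _normalize(rmsd, f, convention)


def gat_search(
    onsets,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    df: float = DEFAULT_DF,
    *,
    convention: str = "rmsd_times_f",
    optimize_phase: bool = False,
    prefer_fundamental: bool = True,
    max_grid_points: int = MAX_GRID_POINTS,
) -> GATResult:
    """Evaluate FRMSD on the inclusive frequency grid and return the best beat.

    The best beat is the global FRMSD minimum; exact ties resolve to the
    slowest (lowest) frequency, which selects the fundamental when harmonics
    fit equally well.  With ``prefer_fundamental`` (the default), a winner
    that fits perfectly (FRMSD at the tie tolerance) is additionally refined
    to its slowest perfectly-fitting integer subharmonic within the window,
    even when that frequency falls between grid points — an isochronous
    sequence whose period is not a multiple of 0.01 Hz in frequency would
    otherwise be reported at an exactly-representable harmonic instead of
    its fundamental.
    """
    t = _check_onsets(onsets)
    if not (f_min > 0 and f_min < f_max and df > 0):
        raise ValidationError("need 0 < f_min < f_max and df > 0")
    n_steps = int(round((f_max - f_min) / df))
    if n_steps + 1 > max_grid_points:
        raise ConfigurationError(
            f"frequency grid of {n_steps + 1} points exceeds cap {max_grid_points}"
        )
    grid = f_min + df * np.arange(n_steps + 1)
    if grid[-1] > f_max + 1e-9:
        grid = grid[grid <= f_max + 1e-9]

    rel = t - t[0]
    if optimize_phase:
        rmsd = np.array([_phase_optimal_rmsd(rel, float(f)) for f in grid])
    else:
        # chunk to bound the (n_freqs x n_onsets) scratch array
        chunk = max(1, int(5e6 / max(1, rel.size)))
        parts = []
        for i in range(0, grid.size, chunk):
            dev = _deviations(rel, grid[i : i + chunk])
            parts.append(np.sqrt(np.mean(dev**2, axis=1)))
        rmsd = np.concatenate(parts)
    frmsd = _normalize(rmsd, grid, convention)
    # slowest frequency among ties; minima within 1e-10 (dimensionless) are
    # treated as exact so harmonics of a perfect fit cannot outrank the
    # fundamental through rounding noise
    tie_tol = 1e-10
    k = int(np.argmax(frmsd <= frmsd.min() + tie_tol))
    best_f = float(grid[k])
    best_frmsd = float(frmsd[k])
    best_rmsd = float(rmsd[k])
    if prefer_fundamental and best_frmsd <= tie_tol and not optimize_phase:
        for m in range(int(best_f / f_min), 1, -1):  # slowest candidate first
            cand = best_f / m
            if cand < f_min - 1e-12:
                continue
            dev = _deviations(rel, np.asarray([cand]))[0]
            r = float(np.sqrt(np.mean(dev**2)))
            fr = float(_normalize(r, cand, convention))
            if fr <= tie_tol:
                best_f, best_frmsd, best_rmsd = cand, fr, r
                break
    return GATResult(
        grid=grid,
        frmsd_curve=frmsd,
        best_frequency=best_f,
        best_frmsd=best_frmsd,
        rmsd_at_best=best_rmsd,
        convention=convention,
    )


def _check_onsets(onsets) -> np.ndarray:
    t = np.asarray(onsets, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValidationError("GAT needs >= 2 onset times")
    if not np.all(np.isfinite(t)):
        raise ValidationError("onsets must be finite")
    return np.sort(t)


def _normalize(rmsd, f, convention: str):
    if convention == "rmsd_times_f":
        return rmsd * f
    if convention == "rmsd_over_f":
        return rmsd / f
    raise ConfigurationError(
        f"convention must be 'rmsd_times_f' or 'rmsd_over_f', got {convention!r}"
    )


def _phase_optimal_rmsd(rel: np.ndarray, f: float) -> float:
    """RMSD minimized over the beat-grid phase.

    The squared distance to the nearest beat is a function of the onset phase
    angle; the RMS is minimized at the phase offset whose wrapped deviations
    have zero circular mean.  A fine scan over one period (with local
    refinement) is robust to the piecewise nature of the wrapped distance.
    """
    period = 1.0 / f
    offsets = np.linspace(0.0, period, 201, endpoint=False)
    phase = np.mod(rel[None, :] - offsets[:, None], period)
    dev = np.minimum(phase, period - phase)
    cost = np.mean(dev**2, axis=1)
    k = int(np.argmin(cost))
    lo = offsets[k] - period / 200
    hi = offsets[k] + period / 200
    fine = np.linspace(lo, hi, 101)
    phase = np.mod(rel[None, :] - fine[:, None], period)
    dev = np.minimum(phase, period - phase)
    cost = np.mean(dev**2, axis=1)
    return float(np.sqrt(cost.min()))
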