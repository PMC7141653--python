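"""Full-analysis orchestration, prominent beat categories and the
method-selection decision cascade.

``run_analysis`` runs every method on a dataset — IOI summary, per-sequence
beat frequencies by IOI, FFT and GAT, goodness-of-fit values, 10-Hz-wide
prominent beat categories, per-individual beat clustering, recurrence
matrices — and a rule-based recommendation of which beat method suits the
data.  Every threshold the cascade uses is recorded in the report so results
remain comparable across studies.

The decision cascade asks, in order:

1. Is the dataset periodic at all?  A unimodal IOI distribution with
   moderate per-sequence variability says yes; an aperiodic control (IOIs
   uniform on (0,1)) fails on nPVI and CV.
2. Is it isochronous?  A very low mean nPVI is strict isochrony; a middle
   nPVI (< 40) still admits isochrony when per-sequence CV* is low.
3. Which method?  A large gap between pooled CV* and the per-sequence mean
   CV* — or a high nPVI — signals likely individual differences, where a
   plain IOI mean oversimplifies and the GAT search is preferred.  Short
   sequences (median duration under ~1 s) are routed away from the FFT,
   whose frequency resolution 1/(N*dt) is then too coarse; tempo-changing
   sequences are routed away from GAT, which fits a single frequency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import cluster_report
from .errors import InsufficientDataError, ValidationError
from .fourier import binarize_onsets, fft_best_beat
from .gat import gat_search
from .ioi_stats import DatasetSummary, beat_from_mean_ioi, dataset_summary
from .recurrence import recurrence_matrix, render_recurrence
from .sequence_io import Dataset, onsets_from_iois

logger = logging.getLogger("rhythmkit")

__all__ = [
    "ProminentCategory",
    "MethodRecommendation",
    "AnalysisConfig",
    "prominent_category",
    "decide_method",
    "count_modes",
    "run_analysis",
]


@dataclass(frozen=True)
class ProminentCategory:
    """The 10-Hz-wide bin holding the largest share of best beats."""

    category: str
    low: float
    high: float
    share: float  # percent of sequences, 0-100


@dataclass(frozen=True)
class MethodRecommendation:
    """Outcome of the decision cascade with its full rule trail."""

    periodic: str                 # yes / no / unclear
    isochronous: str              # yes / no / unclear
    individual_differences_likely: bool
    recommended_methods: tuple[str, ...]
    rationale: tuple[str, ...]
    thresholds_used: dict


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis settings with their package defaults."""

    dt: float = 0.005                 # raster resolution, s (200 Hz sampling)
    f_max_fft: float = 100.0          # FFT search band upper edge, Hz
    gat_f_min: float = 2.0            # GAT grid, Hz
    gat_f_max: float = 100.0
    gat_df: float = 0.01
    gat_convention: str = "rmsd_times_f"
    ngof_length_units: str = "samples"
    cluster_threshold: float = 0.05   # dissimilarity cut, Hz
    cluster_normalize: bool = False
    category_width: float = 10.0      # prominent-category bin width, Hz
    npvi_strict_isochrony: float = 15.0
    npvi_isochrony_max: float = 40.0
    cv_isochrony_max: float = 0.3
    npvi_aperiodic: float = 60.0
    cv_periodic_max: float = 0.5
    npvi_individual: float = 30.0     # nPVI mean at/above which individual
                                      # differences are considered likely
    cv_gap_max: float = 0.1           # gap strictly above this -> likely
    fft_min_duration: float = 1.0     # s; median below -> FFT inadequate
    tempo_slope_max: float = 0.2      # relative IOI drift flagged as tempo change

    def to_dict(self) -> dict:
        return asdict(self)


def prominent_category(beats, bin_width: float = 10.0) -> ProminentCategory:
    """Modal half-open frequency bin [k*w, (k+1)*w) and its percentage share.

    Ties break toward the lower bin.  Beats exactly at the top of the
    analysis band fall in the final bin.
    """
    f = np.asarray(beats, dtype=float)
    if f.size < 1:
        raise InsufficientDataError("prominent_category needs >= 1 beat")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if np.any(f < 0):
        raise ValidationError("beat frequencies must be non-negative")
    bins = np.floor(f / bin_width).astype(int)
    counts = np.bincount(bins)
    k = int(np.argmax(counts))  # first maximum -> lower bin wins ties
    lo, hi = k * bin_width, (k + 1) * bin_width
    return ProminentCategory(
        category=f"{lo:g}–{hi:g} Hz",
        low=lo,
        high=hi,
        share=100.0 * counts[k] / f.size,
    )


def count_modes(iois, *, n_bins: int | None = None, min_prominence: float = 0.25) -> int:
    """Number of modes of the IOI distribution on a histogram binning.

    The bin count defaults to sqrt(n) clipped to [5, 15] and the histogram is
    lightly smoothed (3-bin moving average), so single-bin sampling noise
    does not register; a mode is a local maximum whose height exceeds
    ``min_prominence`` of the tallest bar.  This is a descriptive stand-in
    for the visual unimodality judgement, not a formal test.
    """
    x = np.asarray(iois, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("count_modes needs >= 2 IOIs")
    span = x.max() - x.min()
    if span <= 1e-12 * max(1.0, x.max()):  # degenerate: effectively constant
        return 1
    if n_bins is None:
        n_bins = int(np.clip(np.sqrt(x.size), 5, 15))
    counts, _ = np.histogram(x, bins=n_bins)
    counts = np.convolve(counts.astype(float), np.ones(3) / 3, mode="same")
    floor = min_prominence * counts.max()
    padded = np.concatenate([[-1], counts, [-1]])
    modes = 0
    for i in range(1, len(padded) - 1):
        if (
            padded[i] > floor
            and padded[i] >= padded[i - 1]
            and padded[i] > padded[i + 1]
        ):
            modes += 1
    return max(modes, 1)


def decide_method(
    summary: DatasetSummary,
    seq_durations=None,
    config: AnalysisConfig | None = None,
    *,
    unimodal: bool | None = None,
    tempo_changing: bool = False,
) -> MethodRecommendation:
    """Apply the decision cascade to a dataset summary.

    ``seq_durations`` defaults to the summary's own per-sequence durations;
    ``unimodal`` may be supplied when the pooled IOIs are not at hand (e.g.
    when working from a published summary table); when None the distribution
    is treated as unimodal only if nothing else argues against periodicity,
    and the verdict notes the assumption.
    """
    cfg = config or AnalysisConfig()
    if seq_durations is None:
        seq_durations = summary.sequence_durations
    durations = np.asarray(seq_durations, dtype=float)
    rationale: list[str] = []

    # --- 1: periodicity ------------------------------------------------
    if unimodal is None:
        unimodal_known = False
        rationale.append("unimodality not assessed; assumed from context")
        unimodal = True
    else:
        unimodal_known = True
        rationale.append(
            f"IOI distribution {'unimodal' if unimodal else 'not unimodal'}"
        )
    periodic = "yes"
    if not unimodal:
        periodic = "unclear"
        rationale.append("multimodal IOI distribution: periodicity unclear")
    if summary.npvi_mean >= cfg.npvi_aperiodic:
        periodic = "no"
        rationale.append(
            f"mean nPVI {summary.npvi_mean:.1f} >= {cfg.npvi_aperiodic:g}: aperiodic"
        )
    if summary.cv_sequence_mean >= cfg.cv_periodic_max:
        periodic = "no"
        rationale.append(
            f"per-sequence CV* {summary.cv_sequence_mean:.2f} >= "
            f"{cfg.cv_periodic_max:g}: aperiodic"
        )
    if periodic == "yes":
        rationale.append(
            f"periodic: unimodal IOIs, mean nPVI {summary.npvi_mean:.1f} < "
            f"{cfg.npvi_aperiodic:g}, per-sequence CV* "
            f"{summary.cv_sequence_mean:.2f} < {cfg.cv_periodic_max:g}"
        )

    # --- 2: isochrony ---------------------------------------------------
    if periodic == "no":
        isochronous = "no"
    elif summary.npvi_mean < cfg.npvi_strict_isochrony:
        isochronous = "yes"
        rationale.append(
            f"mean nPVI {summary.npvi_mean:.1f} < {cfg.npvi_strict_isochrony:g}: "
            "strict isochrony"
        )
    elif (
        summary.npvi_mean < cfg.npvi_isochrony_max
        and summary.cv_sequence_mean < cfg.cv_isochrony_max
    ):
        isochronous = "yes"
        rationale.append(
            f"mean nPVI {summary.npvi_mean:.1f} in middle band (< "
            f"{cfg.npvi_isochrony_max:g}) with low per-sequence CV* "
            f"{summary.cv_sequence_mean:.2f}: consistent with isochrony"
        )
    else:
        isochronous = "unclear"
        rationale.append("variability indices leave isochrony unclear")

    # --- 3: individual differences and method choice --------------------
    indiv = (
        summary.npvi_mean >= cfg.npvi_individual
        or summary.cv_gap > cfg.cv_gap_max
    )
    rationale.append(
        f"CV gap {summary.cv_gap:.2f} "
        f"{'>' if summary.cv_gap > cfg.cv_gap_max else '<='} {cfg.cv_gap_max:g}"
        f"; mean nPVI {summary.npvi_mean:.1f} "
        f"{'>=' if summary.npvi_mean >= cfg.npvi_individual else '<'} "
        f"{cfg.npvi_individual:g} -> individual differences "
        f"{'likely' if indiv else 'unlikely'}"
    )

    methods: list[str] = []
    if periodic == "no":
        rationale.append("aperiodic: no beat method recommended")
    else:
        median_dur = float(np.median(durations)) if durations.size else 0.0
        fft_ok = median_dur >= cfg.fft_min_duration
        rationale.append(
            f"median sequence duration {median_dur:.2f} s "
            f"{'>=' if fft_ok else '<'} {cfg.fft_min_duration:g} s: FFT "
            f"{'adequate' if fft_ok else 'inadequate (frequency resolution too coarse)'}"
        )
        if indiv:
            if tempo_changing:
                methods = ["recurrence"]
                rationale.append(
                    "tempo-changing sequences: GAT single-frequency fit "
                    "unsuitable; inspect recurrence structure"
                )
            else:
                methods = ["GAT"]
                rationale.append(
                    "individual differences likely: per-sequence GAT search "
                    "preferred over the oversimplifying IOI mean"
                )
        else:
            methods = ["IOI", "FFT"] if fft_ok else ["IOI", "GAT"]
            rationale.append(
                "no strong individual differences: "
                + (" / ".join(methods))
                + " suffice"
            )
        if isochronous == "unclear":
            methods.append("recurrence")
            rationale.append("isochrony unclear: add recurrence plots")
    return MethodRecommendation(
        periodic=periodic,
        isochronous=isochronous,
        individual_differences_likely=bool(indiv),
        recommended_methods=tuple(methods),
        rationale=tuple(rationale),
        thresholds_used=cfg.to_dict(),
    )


def _tempo_changing(iois: np.ndarray, max_rel_slope: float) -> bool:
    """Flag a monotone drift of the IOI series beyond a relative slope cap."""
    if iois.size < 4:
        return False
    x = np.arange(iois.size)
    slope = np.polyfit(x, iois, 1)[0]
    total_drift = slope * (iois.size - 1) / iois.mean()
    return abs(total_drift) > max_rel_slope


def run_analysis(
    ds: Dataset,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    *,
    render_plots: bool = False,
) -> dict:
    """Run every method on a dataset and assemble the report bundle.

    Returns a dict with keys ``summary`` (DatasetSummary), ``beats``
    (per-sequence DataFrame: IOI/FFT/GAT beats and goodness-of-fit),
    ``prominent`` (per-method ProminentCategory), ``clusters`` (per-
    individual table), ``recommendation`` (MethodRecommendation), ``config``
    (the settings snapshot) and ``qc`` (per-sequence failures and warnings).
    With ``out_dir`` the tables are written as CSV, the recommendation as
    JSON and, if ``render_plots``, histogram panels and recurrence plots as
    PNG.
    """
    cfg = config or AnalysisConfig()
    summary = dataset_summary(ds)
    qc: list[str] = []

    rows = []
    tempo_flags = []
    for seq in ds.ioi_sequences():
        if len(seq) < 2:
            qc.append(f"{seq.sequence_id}: < 2 IOIs, skipped")
            continue
        onsets = onsets_from_iois(seq).onsets
        row: dict = dict(
            sequence_id=seq.sequence_id,
            individual=seq.individual_id,
            species=seq.species,
            n_iois=len(seq),
            duration_s=seq.duration,
        )
        row["ioi_beat_hz"] = beat_from_mean_ioi(seq.iois)
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                binary = binarize_onsets(onsets, cfg.dt)
                spec = fft_best_beat(
                    binary, cfg.f_max_fft, length_units=cfg.ngof_length_units
                )
            row.update(
                fft_beat_hz=spec.best_frequency,
                fft_gof=spec.gof,
                fft_ngof=spec.ngof,
                fft_resolution_hz=spec.freq_resolution,
                p0=spec.p0,
            )
            if binary.n_collisions:
                qc.append(f"{seq.sequence_id}: {binary.n_collisions} onset collision(s)")
        except Exception as exc:  # collected, not fatal
            qc.append(f"{seq.sequence_id}: FFT failed ({exc})")
        try:
            gat = gat_search(
                onsets, cfg.gat_f_min, cfg.gat_f_max, cfg.gat_df,
                convention=cfg.gat_convention,
            )
            row.update(
                gat_beat_hz=gat.best_frequency,
                gat_frmsd=gat.best_frmsd,
                gat_rmsd_s=gat.rmsd_at_best,
            )
        except Exception as exc:
            qc.append(f"{seq.sequence_id}: GAT failed ({exc})")
        tempo_flags.append(_tempo_changing(seq.iois, cfg.tempo_slope_max))
        rows.append(row)
    beats = pd.DataFrame(rows)

    prominent = {}
    for method, col in [("IOI", "ioi_beat_hz"), ("FFT", "fft_beat_hz"), ("GAT", "gat_beat_hz")]:
        if col in beats and beats[col].notna().any():
            prominent[method] = prominent_category(
                beats[col].dropna().to_numpy(), cfg.category_width
            )

    beats_by_method: dict[str, dict[str, list[float]]] = {}
    for method, col in [("GAT", "gat_beat_hz"), ("FFT", "fft_beat_hz"), ("IOI", "ioi_beat_hz")]:
        if col not in beats:
            continue
        per_ind: dict[str, list[float]] = {}
        for ind, grp in beats.groupby("individual"):
            per_ind[str(ind)] = grp[col].dropna().tolist()
        beats_by_method[method] = per_ind
    clusters = cluster_report(
        beats_by_method, cfg.cluster_threshold, normalize=cfg.cluster_normalize
    )

    pooled = ds.pooled_iois()
    unimodal = count_modes(pooled) == 1
    tempo_changing = bool(np.mean(tempo_flags) > 0.5) if tempo_flags else False
    recommendation = decide_method(
        summary,
        config=cfg,
        unimodal=unimodal,
        tempo_changing=tempo_changing,
    )

    report = dict(
        summary=summary,
        beats=beats,
        prominent=prominent,
        clusters=clusters,
        recommendation=recommendation,
        config=cfg.to_dict(),
        qc=qc,
    )
    if out_dir is not None:
        _write_report(ds, report, Path(out_dir), cfg, render_plots)
    return report


def _summary_frame(summary: DatasetSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                dataset=summary.name,
                mean_ioi_s=summary.mean_ioi,
                sd_ioi_s=summary.sd_ioi,
                cv_overall=summary.cv_overall,
                cv_sequence_mean=summary.cv_sequence_mean,
                ioi_min_s=summary.ioi_range[0],
                ioi_max_s=summary.ioi_range[1],
                n_iois=summary.n_iois,
                npvi_min=min(summary.npvi_per_sequence),
                npvi_max=max(summary.npvi_per_sequence),
                npvi_mean=summary.npvi_mean,
                npvi_overall=summary.npvi_overall,
                n_sequences=summary.n_sequences,
            )
        ]
    )


def _write_report(ds, report, out_dir: Path, cfg, render_plots: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _summary_frame(report["summary"]).to_csv(out_dir / "summary.csv", index=False)
    report["beats"].to_csv(out_dir / "beats.csv", index=False)
    report["clusters"].to_csv(out_dir / "clusters.csv", index=False)
    rec = report["recommendation"]
    payload = dict(
        periodic=rec.periodic,
        isochronous=rec.isochronous,
        individual_differences_likely=rec.individual_differences_likely,
        recommended_methods=list(rec.recommended_methods),
        rationale=list(rec.rationale),
        thresholds_used=rec.thresholds_used,
        prominent_categories={
            m: dict(category=p.category, share_percent=p.share)
            for m, p in report["prominent"].items()
        },
        qc=report["qc"],
    )
    (out_dir / "recommendation.json").write_text(json.dumps(payload, indent=2))
    if render_plots:
        _histogram_panel(ds, report["beats"], out_dir / "histograms.png")
        plots = out_dir / "recurrence"
        plots.mkdir(exist_ok=True)
        for seq in ds.ioi_sequences():
            if len(seq) >= 2:
                M = recurrence_matrix(seq.iois, sequence_id=seq.sequence_id)
                render_recurrence(M, plots / f"{seq.sequence_id}.png")


def _histogram_panel(ds, beats: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cols = [
        ("IOI distribution", None),
        ("IOI beats", "ioi_beat_hz"),
        ("FFT beats", "fft_beat_hz"),
        ("GAT beats", "gat_beat_hz"),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3))
    pooled = ds.pooled_iois()
    span = (float(pooled.min()) - 1e-6, float(pooled.max()) + 1e-6)
    axes[0].hist(pooled, bins=30, range=span, color="0.4")
    axes[0].set_xlabel("IOI (s)")
    for ax, (title, col) in zip(axes, cols):
        ax.set_title(title, fontsize=9)
        if col is not None:
            if col in beats and beats[col].notna().any():
                ax.hist(beats[col].dropna(), bins=np.arange(0, 105, 5), color="0.4")
            ax.set_xlabel("beat (Hz)")
        ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
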