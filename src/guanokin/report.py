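"""Smoothers, phase classification, hysteresis paths and figure output.

Smoothers: a centred moving average (edge-truncated) and a polynomial
trend in log_e time — both linear operators.  Phases partition the
post-feeding timeline at the physiological landmarks (ingestion/
digestion knot at 120 min, gut-emptying onset at 12.5 h, gut void at
52.5 h, starvation onset at 10 d).  Hysteresis between paired series
(gut size leading, Malpighian guanine lagging) is summarised as a
time-ordered path with its signed enclosed (shoelace) area.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import PhaseLandmarks, register_result


@register_result
@dataclass
class SmoothedSeries:
    times: list
    values: list
    method: str           # "moving_average" or "polynomial"
    window_or_degree: int


class Phase(str, enum.Enum):
    INGESTION_FILLING = "ingestion_filling"
    DIGESTION_FILLING_DOMINANT = "digestion_filling_dominant"
    DIGESTION_EMPTYING = "digestion_emptying"
    POST_DIGESTIVE_EXCRETION = "post_digestive_excretion"
    STARVATION = "starvation"


def moving_average(
    times: Sequence[float],
    values: Sequence[float],
    window: int,
    centred: bool = True,
) -> SmoothedSeries:
    """Centred (default) or trailing moving average, truncated at edges.

    The "order" of a moving-average smoother is read as its window
    size in points; window 1 is the identity.
    """
    t = list(map(float, times))
    y = np.asarray(values, dtype=float)
    if len(y) == 0:
        raise ValueError("series must be non-empty")
    if not 1 <= window <= len(y):
        raise ValueError("window must be in [1, len(series)]")
    out = np.empty_like(y)
    half = (window - 1) // 2
    for i in range(len(y)):
        if centred:
            lo = max(0, i - half)
            hi = min(len(y), i + (window - half))
        else:
            lo = max(0, i - window + 1)
            hi = i + 1
        out[i] = y[lo:hi].mean()
    return SmoothedSeries(
        times=t, values=list(out), method="moving_average", window_or_degree=window
    )


def polynomial_trend(
    times: Sequence[float], values: Sequence[float], degree: int
) -> SmoothedSeries:
    """Least-squares polynomial in log_e(time), evaluated on the grid.

    Times must be strictly positive (t = 0 is a separate category on
    the log axis and is not admitted here).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.any(t <= 0):
        raise ValueError("polynomial trend requires times > 0 (log scale)")
    if len(t) <= degree:
        raise ValueError("need more points than the polynomial degree")
    x = np.log(t)
    if degree >= 1 and np.ptp(x) == 0:
        raise np.linalg.LinAlgError("degenerate design: all times equal")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    return SmoothedSeries(
        times=list(map(float, t)),
        values=list(fitted),
        method="polynomial",
        window_or_degree=degree,
    )


def classify_phase(t_min: float, landmarks: PhaseLandmarks = PhaseLandmarks()) -> Phase:
    """Assign a post-feeding time (minutes) to its physiological phase.

    The landmark partition covers [0, inf) with no gaps or overlaps:
    [0, knot) ingestion; [knot, emptying onset) slow digestion with net
    filling; [emptying onset, gut void) net emptying; [gut void,
    starvation onset) post-digestive excretion; beyond, starvation.
    """
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    if t_min < landmarks.knot_min:
        return Phase.INGESTION_FILLING
    if t_min < landmarks.emptying_onset_min:
        return Phase.DIGESTION_FILLING_DOMINANT
    if t_min < landmarks.gut_void_min:
        return Phase.DIGESTION_EMPTYING
    if t_min < landmarks.starvation_onset_min:
        return Phase.POST_DIGESTIVE_EXCRETION
    return Phase.STARVATION


@register_result
@dataclass
class HysteresisPath:
    """Time-ordered (x, y) path with its signed enclosed area."""

    times: list
    x: list
    y: list
    signed_area: float

    @property
    def x_peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.x))])

    @property
    def y_peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.y))])


def hysteresis_pairs(
    times: Sequence[float],
    series_x: Sequence[float],
    series_y: Sequence[float],
    times_y: Sequence[float] | None = None,
) -> HysteresisPath:
    """Time-ordered path of paired series with the shoelace signed area.

    Both series must share the common grid ``times`` (``times_y``, if
    given, is checked against it).  A nonzero signed area of the closed
    path indicates hysteresis between the two trajectories.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if times_y is not None and not np.array_equal(t, np.asarray(times_y, dtype=float)):
        raise ValueError("series are on mismatched time grids")
    if not (len(t) == len(x) == len(y)):
        raise ValueError("series are on mismatched time grids")
    order = np.argsort(t)
    t, x, y = t[order], x[order], y[order]
    # shoelace on the closed polygon traced in time order
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return HysteresisPath(
        times=list(t), x=list(x), y=list(y), signed_area=area
    )


# ---------------------------------------------------------------------------
# Figure/report generation
# ---------------------------------------------------------------------------

def _log_axis(times_min: np.ndarray) -> np.ndarray:
    """log_e(minutes); t = 0 is drawn as a separate leftmost category."""
    positive = times_min[times_min > 0]
    floor = np.log(positive.min()) - 1.0 if len(positive) else 0.0
    return np.where(times_min > 0, np.log(np.maximum(times_min, 1e-300)), floor)


def render_report(
    estimates_frame,
    fit,
    score_table,
    out_dir: str | Path,
    landmarks: PhaseLandmarks = PhaseLandmarks(),
) -> list[Path]:
    """Write occurrence/fit, linear-scale, and hysteresis figures plus a
    text summary into ``out_dir``; returns the files written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinetics import predict_M
    from .occurrence import mean_scores

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    t_min = np.asarray(estimates_frame["time_min"], dtype=float)
    m_hat = np.asarray(estimates_frame["posterior_mean"], dtype=float)
    t_h = t_min / 60.0
    grid_h = np.linspace(max(t_h.min(), 0.02), t_h.max(), 600)

    # Occurrence + fitted kinetics on the log_e(min) axis
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(_log_axis(t_min), m_hat, "ko", ms=4, label="posterior mean occurrence")
    sm = moving_average(t_min, m_hat, window=2)
    ax.plot(_log_axis(t_min), sm.values, "k-", lw=0.8, label="2-pt moving average")
    if fit is not None:
        ax.plot(
            _log_axis(grid_h * 60.0),
            predict_M(fit, grid_h),
            color="grey",
            lw=2,
            label=f"stripping fit (n={fit.n:g})",
        )
    ax.axvline(np.log(landmarks.knot_min), color="grey", ls="--", lw=0.8)
    ax.axvline(np.log(landmarks.gut_void_min), color="grey", ls=":", lw=0.8)
    ax.set_xlabel(r"$\log_e$ time (min) since start of feeding")
    ax.set_ylabel("P(Malpighian guanine)")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    p = out_dir / "occurrence_fit.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    # Back-transformed (arithmetic time) view
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(t_h, m_hat, "ko", ms=4)
    if fit is not None:
        ax.plot(grid_h, predict_M(fit, grid_h), color="grey", lw=2)
    ax.set_xlabel("time (h) since start of feeding")
    ax.set_ylabel("P(Malpighian guanine)")
    fig.tight_layout()
    p = out_dir / "occurrence_linear.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    # Hysteresis: mean tubule score against mean rectal-lumen score path
    if score_table is not None:
        ms = mean_scores(score_table)
        pooled = ms.groupby("time_min")["mean_score"].mean()
        lumen = (
            mean_scores(score_table, value="lumen_score")
            .groupby("time_min")["mean_score"]
            .mean()
        )
        path = hysteresis_pairs(pooled.index, lumen.values, pooled.values)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(path.x, path.y, "-o", ms=3, color="grey")
        ax.set_xlabel("mean rectal-vesicle lumen score")
        ax.set_ylabel("mean Malpighian tubule score")
        fig.tight_layout()
        p = out_dir / "hysteresis.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    summary = out_dir / "summary.txt"
    lines = [f"time points: {len(t_min)}", f"peak occurrence: {m_hat.max():.3f}"]
    if fit is not None:
        lines += [
            f"elimination half-life: {fit.t_half_el_h:.1f} h",
            f"input half-life: {fit.t_half_in_h:.1f} h",
            f"cascade power n: {fit.n:g}",
            f"effective input half-life: {fit.t_half_in_effective_h:.1f} h",
        ]
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
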