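"""NOR outcome measures: time courses, discrimination indices, latency,
first-approach, and their cohort-level statistics.

The discrimination index DI = (T_nov - T_fam) / (T_nov + T_fam) lies in
[-1, 1]; +1 means exclusive novel-object exploration.  The headline measure
is the relative (paired) DI, DI_test - DI_sample, which cancels stable side
preferences (nest position, activity history) that inflate or deflate either
phase's DI alone.

Analysis windows follow the study protocol: the sample-phase DI uses the
entire sample phase, the test-phase DI only the first 20 minutes after the
animal's first interaction with either object, where most exploration
concentrates.  Time courses are 1-min binned; Gaussian smoothing is for
display only and never feeds statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .core import ExplorationSeries, PhaseSchedule

__all__ = [
    "BinnedExploration",
    "DIRecord",
    "bin_series",
    "smooth_for_display",
    "discrimination_index",
    "analysis_windows",
    "phase_di",
    "relative_di",
    "latency_and_peak",
    "cohort_peak_values",
    "first_approach",
    "first_approach_cohort",
    "score_session",
    "score_cohort",
    "sample_vs_relative_di_correlation",
]

TEST_WINDOW_S = 1200.0  # first 20 min after the first object interaction


@dataclass
class BinnedExploration:
    """Per-bin exploration seconds per side (bins of ``bin_width_s``)."""

    bin_start_s: np.ndarray
    seconds: dict[str, np.ndarray]  # side -> seconds explored per bin
    bin_width_s: float
    frame_rate: float

    @property
    def total(self) -> np.ndarray:
        return self.seconds["left"] + self.seconds["right"]

    def smoothed(self, sigma_bins: float = 4.0) -> dict[str, np.ndarray]:
        """Display-only smoothed copies of the per-side time courses."""
        return {s: smooth_for_display(v, sigma_bins) for s, v in self.seconds.items()}


@dataclass
class DIRecord:
    """One phase's exploration accounting and discrimination index."""

    phase: str
    window_start_s: float
    window_end_s: float
    t_novel_s: float
    t_familiar_s: float

    @property
    def di(self) -> float:
        return discrimination_index(self.t_novel_s, self.t_familiar_s)

    @property
    def defined(self) -> bool:
        return (self.t_novel_s + self.t_familiar_s) > 0


def bin_series(series: ExplorationSeries, bin_width_s: float = 60.0) -> BinnedExploration:
    """Group per-frame exploration into fixed-width bins of seconds explored.

    Per-bin seconds = true-frame count / frame_rate, so summed bins equal the
    total exploration time exactly (a trailing partial bin is kept).
    """
    period = 1.0 / series.frame_rate
    ratio = bin_width_s / period
    if not np.isclose(ratio, round(ratio)):
        raise ValueError("bin width must be an integer multiple of the frame period")
    frames_per_bin = int(round(ratio))
    n = series.n_frames
    n_bins = int(np.ceil(n / frames_per_bin)) if n else 0
    edges = np.arange(0, n_bins * frames_per_bin, frames_per_bin)
    seconds = {}
    for side in ("left", "right"):
        counts = np.add.reduceat(series.side(side).astype(float), edges) if n else np.zeros(0)
        seconds[side] = counts / series.frame_rate
    return BinnedExploration(
        bin_start_s=edges / series.frame_rate,
        seconds=seconds,
        bin_width_s=bin_width_s,
        frame_rate=series.frame_rate,
    )


def smooth_for_display(values: np.ndarray, sigma_bins: float = 4.0) -> np.ndarray:
    """Gaussian smoothing for plots (sigma in bins, kernel truncated at
    +/- 4 sigma, renormalised at the edges).  Display only — statistics are
    always computed on the unsmoothed values."""
    if sigma_bins < 0:
        raise ValueError("sigma must be non-negative")
    values = np.asarray(values, dtype=float)
    half = int(np.ceil(4.0 * sigma_bins))
    if sigma_bins == 0 or half == 0 or values.size == 0:
        return values.copy()
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kernel /= kernel.sum()
    # explicit centre slice: np.convolve(mode="same") misbehaves when the
    # kernel is longer than the signal
    start = (len(kernel) - 1) // 2
    num = np.convolve(values, kernel, mode="full")[start : start + len(values)]
    den = np.convolve(np.ones_like(values), kernel, mode="full")[start : start + len(values)]
    return num / den


def discrimination_index(t_a_s: float, t_b_s: float) -> float:
    """(t_a - t_b) / (t_a + t_b); NaN (undefined) when both times are zero."""
    if t_a_s < 0 or t_b_s < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_a_s + t_b_s
    if total == 0:
        return float("nan")
    return (t_a_s - t_b_s) / total


def analysis_windows(
    schedule: PhaseSchedule, series: ExplorationSeries
) -> dict[str, tuple[float, float] | None]:
    """Per-phase analysis windows (half-open, seconds).

    sample / retention / habituation use the full phase; the test window is
    the first 20 min from the first exploratory frame on either side within
    the test phase, clipped to the phase end, or None when the animal never
    explored during the test.
    """
    windows: dict[str, tuple[float, float] | None] = {}
    for p in schedule.phases:
        if p.name != "test":
            windows[p.name] = (p.start_s, p.end_s)
            continue
        sl = schedule.frame_slice("test", series.frame_rate)
        any_exp = series.any_explore[sl]
        idx = np.flatnonzero(any_exp)
        if idx.size == 0:
            windows["test"] = None
        else:
            t_first = p.start_s + idx[0] / series.frame_rate
            windows["test"] = (t_first, min(t_first + TEST_WINDOW_S, p.end_s))
    return windows


def _novelty_sides(schedule: PhaseSchedule) -> tuple[str, str]:
    """(novel, familiar) sides; in sample/retention these are the sides where
    the novel/familiar objects will subsequently appear in the test."""
    return schedule.novel_side, schedule.familiar_side


def phase_di(
    series: ExplorationSeries,
    schedule: PhaseSchedule,
    phase: str,
    window: tuple[float, float] | None = None,
    by: str = "novelty",
) -> DIRecord:
    """Exploration accounting for one phase window.

    ``by='novelty'`` orients the index as novel minus familiar (future
    assignment outside the test phase); ``by='side'`` as left minus right,
    ignoring novelty.
    """
    if window is None:
        p = schedule.phase(phase)
        window = (p.start_s, p.end_s)
    sl = series.window_frames(*window)
    if by == "novelty":
        a_side, b_side = _novelty_sides(schedule)
    elif by == "side":
        a_side, b_side = "left", "right"
    else:
        raise ValueError("by must be 'novelty' or 'side'")
    return DIRecord(
        phase=phase,
        window_start_s=window[0],
        window_end_s=window[1],
        t_novel_s=series.seconds(a_side, sl),
        t_familiar_s=series.seconds(b_side, sl),
    )


def relative_di(di_test: float, di_sample: float) -> float:
    """Paired recognition measure DI_test - DI_sample, in [-2, 2]; NaN
    propagates from either undefined index."""
    return di_test - di_sample


def latency_and_peak(
    binned: BinnedExploration,
    series: ExplorationSeries,
    schedule: PhaseSchedule,
    phase: str,
) -> tuple[float, float]:
    """(latency to first exploration from phase start, peak unsmoothed bin).

    Latency is NaN when the phase contains no exploration; the peak is then
    0.  Binning is assumed aligned with the session start.
    """
    p = schedule.phase(phase)
    sl = schedule.frame_slice(phase, series.frame_rate)
    idx = np.flatnonzero(series.any_explore[sl])
    latency = idx[0] / series.frame_rate if idx.size else float("nan")
    in_phase = (binned.bin_start_s >= p.start_s) & (binned.bin_start_s < p.end_s)
    peak = float(binned.total[in_phase].max()) if in_phase.any() else 0.0
    return latency, peak


def cohort_peak_values(
    binned_list: list[BinnedExploration], schedule: PhaseSchedule, phase: str
) -> np.ndarray:
    """Each animal's unsmoothed bin value at the cohort's peak bin.

    The peak bin is the argmax of the cohort-mean time course within the
    phase, determined per group and phase; individual values at that bin are
    returned for statistical comparison.
    """
    p = schedule.phase(phase)
    mask = (binned_list[0].bin_start_s >= p.start_s) & (binned_list[0].bin_start_s < p.end_s)
    stack = np.vstack([b.total[mask] for b in binned_list])
    arg = int(np.argmax(stack.mean(axis=0)))
    return stack[:, arg]


def first_approach(
    series: ExplorationSeries, schedule: PhaseSchedule, phase: str = "test"
) -> str | None:
    """'novel' or 'familiar' according to the side of the first exploratory
    frame in the phase (future test assignment outside the test phase);
    None when the phase has no exploration."""
    sl = schedule.frame_slice(phase, series.frame_rate)
    left = series.explore_left[sl]
    right = series.explore_right[sl]
    idx = np.flatnonzero(left | right)
    if idx.size == 0:
        return None
    side = "left" if left[idx[0]] else "right"
    return "novel" if side == schedule.novel_side else "familiar"


def first_approach_cohort(
    approaches: list[str | None], alternative: str = "greater"
) -> tuple[float, stats.StatResult, int, int]:
    """Cohort proportion of novel-first approaches with an exact binomial
    test against 0.5 (one-sided toward novel-first by default).

    Returns (proportion, test result, n_novel_first, n_scored); animals with
    no exploration are excluded.
    """
    scored = [a for a in approaches if a is not None]
    k = sum(a == "novel" for a in scored)
    n = len(scored)
    if n == 0:
        return float("nan"), stats.StatResult(float("nan"), float("nan"), flag="no scored animals"), 0, 0
    return k / n, stats.exact_binomial(k, n, 0.5, alternative=alternative), k, n


def score_session(
    series: ExplorationSeries, schedule: PhaseSchedule
) -> dict[str, float | str | None]:
    """Full per-animal NOR score card.

    Computes the sample (full 24-h window) and test (first-20-min window)
    discrimination indices by novelty and by side, the relative DI, the
    first-approach side, and per-phase latency / peak-bin values.
    """
    windows = analysis_windows(schedule, series)
    binned = bin_series(series)
    out: dict[str, float | str | None] = {}
    di_by: dict[tuple[str, str], float] = {}
    for phase in ("sample", "test"):
        if not schedule.has_phase(phase):
            continue
        window = windows[phase]
        for by in ("novelty", "side"):
            rec = phase_di(series, schedule, phase, window=window, by=by)
            key = "di" if by == "novelty" else "di_side"
            out[f"{phase}_{key}"] = rec.di
            di_by[(phase, by)] = rec.di
            if by == "novelty":
                out[f"{phase}_t_novel_s"] = rec.t_novel_s
                out[f"{phase}_t_familiar_s"] = rec.t_familiar_s
                out[f"{phase}_window_start_s"] = rec.window_start_s
                out[f"{phase}_window_end_s"] = rec.window_end_s
    out["relative_di"] = relative_di(di_by[("test", "novelty")], di_by[("sample", "novelty")])
    out["relative_di_side"] = relative_di(di_by[("test", "side")], di_by[("sample", "side")])
    out["first_approach"] = first_approach(series, schedule)
    for phase in ("sample", "retention", "test"):
        if schedule.has_phase(phase):
            lat, peak = latency_and_peak(binned, series, schedule, phase)
            out[f"{phase}_latency_s"] = lat
            out[f"{phase}_peak_bin_s"] = peak
    out["novel_side"] = schedule.novel_side
    return out


def score_cohort(
    series_list: list[ExplorationSeries], schedules: list[PhaseSchedule]
) -> pd.DataFrame:
    """Score every animal and return the tidy per-mouse table."""
    rows = [
        {"mouse": i, **score_session(series, sched)}
        for i, (series, sched) in enumerate(zip(series_list, schedules))
    ]
    return pd.DataFrame(rows)


def sample_vs_relative_di_correlation(
    cohort: pd.DataFrame, at: str = "novel"
) -> stats.StatResult:
    """Pearson correlation between sample-phase exploration time at the
    future-novel (or future-familiar) side and the relative DI.

    The study's observation: longer sample-phase exploration of the object
    at the future novel location predicts weaker 24-h recognition.
    """
    col = "sample_t_novel_s" if at == "novel" else "sample_t_familiar_s"
    sub = cohort[[col, "relative_di"]].dropna()
    return stats.pearson(sub[col].to_numpy(), sub["relative_di"].to_numpy())
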