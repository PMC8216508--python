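"""Quantification of evoked glutamate transients at single boutons.

Single-bouton movies of a membrane-bound, low-affinity glutamate sensor are
converted to ΔF/F (percent of the per-pixel mean baseline fluorescence), and
the population of suprathreshold pixels ("active area") is tracked over time.
Four readouts are derived per frame:

* active area — area occupied by suprathreshold pixels (μm² and fraction of
  the bouton mask),
* cumulative amplitude — spatial integral (sum) of ΔF/F over suprathreshold
  pixels (%·pixel),
* mean amplitude — mean ΔF/F over suprathreshold pixels (a proxy for the
  cleft glutamate concentration),
* maximal amplitude — maximum ΔF/F over suprathreshold pixels (glutamate
  concentration near release sites).

Per-stimulus peaks, paired-pulse ratios, the monoexponential decay constant
of the cumulative transient, and the virtual bouton diameter complete the
per-bouton summary.

Conventions: time in ms, ΔF/F in %, areas in μm².  A pixel is "active" when
its ΔF/F exceeds ``threshold_k`` × that pixel's own baseline SD; the baseline
is the 50-ms window preceding the first stimulus, and both the signal and the
SD come from the same 100-Hz low-pass-filtered trace (a config switch allows
thresholding the unfiltered signal instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "FluorescenceMovie",
    "DffMovie",
    "TransientTraces",
    "TransientSummary",
    "DecayFitError",
    "compute_dff",
    "trace_parameters",
    "peak_and_ppr",
    "fit_decay_tau",
    "virtual_diameter",
    "correlate_parameters",
    "longitudinal_track",
    "BASELINE_MS",
    "TRACE_KINDS",
]

#: Length of the pre-stimulus baseline window (ms).
BASELINE_MS = 50.0

#: Trace readouts summarised per stimulus.
TRACE_KINDS = ("active_area", "cumulative", "mean", "max")


@dataclass
class FluorescenceMovie:
    """Raw single-channel movie of one bouton.

    data: (frames, rows, cols) fluorescence in a.u.
    frame_interval: ms between frames.
    pixel_size: μm per pixel.
    stimulus_times: stimulus onsets in ms from movie start.
    bouton_mask: boolean (rows, cols) contour of the bouton.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    stimulus_times: Sequence[float]
    bouton_mask: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bouton_mask = np.asarray(self.bouton_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (frames, rows, cols)")
        if self.bouton_mask.shape != self.data.shape[1:]:
            raise ValueError("bouton_mask shape must match frame shape")
        if not self.bouton_mask.any():
            raise ValueError("bouton_mask is empty")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        dur = self.data.shape[0] * self.frame_interval
        self.stimulus_times = tuple(float(t) for t in self.stimulus_times)
        if any(t < 0 or t >= dur for t in self.stimulus_times):
            raise ValueError("stimulus_times must lie within the movie duration")

    @property
    def time(self) -> np.ndarray:
        """Frame times in ms (frame centers at k * frame_interval)."""
        return np.arange(self.data.shape[0]) * self.frame_interval


@dataclass
class DffMovie:
    """ΔF/F movie (%) with per-pixel baseline statistics."""

    dff: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    frame_interval: float
    pixel_size: float
    stimulus_times: tuple
    bouton_mask: np.ndarray
    threshold_k: float = 3.0
    filter_cutoff: float | None = 100.0

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.dff.shape[0]) * self.frame_interval


@dataclass
class TransientTraces:
    """Time-resolved readouts of the suprathreshold-pixel population.

    ``mean_amp``/``max_amp`` are NaN on frames with no active pixel (flagged
    in ``has_active``); ``cumulative`` is 0 there (sum over the empty set).
    """

    time: np.ndarray
    active_area: np.ndarray          # μm²
    active_fraction: np.ndarray      # of bouton-mask area
    cumulative: np.ndarray           # %·pixel
    mean_amp: np.ndarray             # %
    max_amp: np.ndarray              # %
    has_active: np.ndarray           # bool per frame
    active_mask_per_frame: np.ndarray  # (frames, rows, cols) bool
    pixel_size: float = np.nan
    stimulus_times: tuple = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time,
                "active_area_um2": self.active_area,
                "active_fraction": self.active_fraction,
                "cumulative_pct_px": self.cumulative,
                "mean_amp_pct": self.mean_amp,
                "max_amp_pct": self.max_amp,
            }
        )


@dataclass
class TransientSummary:
    """Per-stimulus peaks and paired-pulse ratios for each trace kind."""

    peaks: dict                      # kind -> array over stimuli
    ppr: dict                        # kind -> float or None
    ppr_missing_reason: dict = field(default_factory=dict)
    decay_tau: float | None = None
    virtual_diameter: float | None = None
    fraction_active_at_peak: float | None = None

    def as_dict(self) -> dict:
        out = {}
        for kind in self.peaks:
            for i, p in enumerate(np.atleast_1d(self.peaks[kind])):
                out[f"peak{i + 1}_{kind}"] = float(p)
            out[f"ppr_{kind}"] = self.ppr.get(kind)
        out["decay_tau_ms"] = self.decay_tau
        out["virtual_diameter_um"] = self.virtual_diameter
        out["fraction_active_at_peak"] = self.fraction_active_at_peak
        return out


class DecayFitError(RuntimeError):
    """Monoexponential decay fit failed or produced a non-decaying τ."""


def _lowpass(traces: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass along the time axis."""
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, traces, axis=0)


def compute_dff(
    movie: FluorescenceMovie,
    threshold_k: float = 3.0,
    filter_cutoff: float | None = 100.0,
    threshold_on_filtered: bool = True,
) -> DffMovie:
    """Convert a movie to ΔF/F (%) with per-pixel baseline statistics.

    Each pixel trace is low-pass filtered at ``filter_cutoff`` (Hz; None
    disables filtering), then expressed as percent change relative to that
    pixel's mean over the 50 ms preceding the first stimulus.  The per-pixel
    baseline SD is the SD of the (filtered) ΔF/F over the same window.

    ``threshold_on_filtered=False`` computes ΔF/F and the SD on the raw
    traces instead (sensitivity analysis for the filtering choice).
    """
    if not movie.stimulus_times:
        raise ValueError("movie has no stimulus_times")
    first = min(movie.stimulus_times)
    if first < BASELINE_MS:
        raise ValueError(
            f"first stimulus at {first:g} ms but a {BASELINE_MS:g}-ms "
            "pre-stimulus baseline is required"
        )
    fs = 1000.0 / movie.frame_interval
    data = movie.data
    if filter_cutoff is not None and threshold_on_filtered:
        if filter_cutoff >= fs / 2:
            raise ValueError("filter_cutoff must be below the Nyquist frequency")
        data = _lowpass(data, filter_cutoff, fs)

    t = movie.time
    base = (t >= first - BASELINE_MS) & (t < first)
    if base.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 frames")
    baseline_mean = data[base].mean(axis=0)

    zero = (baseline_mean == 0) & movie.bouton_mask
    if zero.any():
        r, c = np.argwhere(zero)[0]
        raise ValueError(f"zero baseline mean in bouton pixel (row={r}, col={c})")
    denom = np.where(baseline_mean == 0, np.nan, baseline_mean)

    dff = (data - baseline_mean) / denom * 100.0
    dff = np.nan_to_num(dff, nan=0.0)
    baseline_sd = dff[base].std(axis=0, ddof=0)
    return DffMovie(
        dff=dff,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        stimulus_times=tuple(movie.stimulus_times),
        bouton_mask=movie.bouton_mask,
        threshold_k=threshold_k,
        filter_cutoff=filter_cutoff,
    )


def trace_parameters(
    dff: DffMovie,
    bouton_mask: np.ndarray | None = None,
    pixel_size: float | None = None,
) -> TransientTraces:
    """Track the suprathreshold-pixel population over time.

    A pixel is active on a frame when its ΔF/F strictly exceeds
    ``threshold_k`` × its own baseline SD.  All pixels of the ROI take part;
    the bouton mask only normalizes the active fraction, so the active area
    may exceed the bouton (release is read out at the membrane and slightly
    beyond it).
    """
    mask = dff.bouton_mask if bouton_mask is None else np.asarray(bouton_mask, bool)
    px = dff.pixel_size if pixel_size is None else float(pixel_size)
    # tiny absolute floor keeps float roundoff of an exactly-constant movie
    # from registering as suprathreshold when the baseline SD is 0
    thr = np.maximum(dff.threshold_k * dff.baseline_sd, 1e-9)
    active = dff.dff > thr  # (frames, rows, cols)

    n_active = active.sum(axis=(1, 2))
    cumulative = np.where(active, dff.dff, 0.0).sum(axis=(1, 2))
    has_active = n_active > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_amp = np.where(has_active, cumulative / np.maximum(n_active, 1), np.nan)
    masked = np.where(active, dff.dff, -np.inf)
    max_amp = np.where(has_active, masked.max(axis=(1, 2)), np.nan)

    area = n_active * px**2
    bouton_area = mask.sum() * px**2
    return TransientTraces(
        time=dff.time,
        active_area=area,
        active_fraction=area / bouton_area,
        cumulative=cumulative,
        mean_amp=mean_amp,
        max_amp=max_amp,
        has_active=has_active,
        active_mask_per_frame=active,
        pixel_size=px,
        stimulus_times=dff.stimulus_times,
    )


def _window_slices(time, stimulus_times, window):
    """Per-stimulus index windows [stim, stim + window), closing at the next
    stimulus if that comes sooner."""
    stims = sorted(stimulus_times)
    out = []
    for i, s in enumerate(stims):
        end = s + window
        if i + 1 < len(stims):
            end = min(end, stims[i + 1])
        out.append((time >= s) & (time < end))
    return out


def peak_and_ppr(
    traces: TransientTraces,
    stimulus_times: Sequence[float] | None = None,
    window: float = 50.0,
) -> TransientSummary:
    """Per-stimulus peaks and paired-pulse ratios (second / first peak).

    The peak is the maximum of each trace within [stimulus, stimulus +
    window); windows close at the next stimulus.  PPR is reported per trace
    kind and is missing (with a reason) when the first peak is 0 or
    undefined.
    """
    stims = traces.stimulus_times if stimulus_times is None else tuple(stimulus_times)
    if not stims:
        raise ValueError("at least one stimulus is required")
    wins = _window_slices(traces.time, stims, window)
    if any(not w.any() for w in wins):
        raise ValueError("a stimulus window contains no frames")

    series = {
        "active_area": traces.active_area,
        "cumulative": traces.cumulative,
        "mean": traces.mean_amp,
        "max": traces.max_amp,
    }
    peaks, ppr, why = {}, {}, {}
    for kind, y in series.items():
        pk = []
        for w in wins:
            seg = y[w]
            pk.append(np.nanmax(seg) if np.isfinite(seg).any() else 0.0)
        pk = np.array(pk)
        peaks[kind] = pk
        if len(pk) >= 2:
            if pk[0] > 0:
                ppr[kind] = float(pk[1] / pk[0])
            else:
                ppr[kind] = None
                why[kind] = "first peak is zero; PPR undefined"
        else:
            ppr[kind] = None
            why[kind] = "fewer than two stimuli"

    frac = None
    if traces.stimulus_times or stimulus_times:
        w0 = wins[0]
        idx = np.flatnonzero(w0)
        if idx.size:
            frac = float(traces.active_fraction[idx[np.argmax(traces.active_area[w0])]])
    return TransientSummary(peaks=peaks, ppr=ppr, ppr_missing_reason=why,
                            fraction_active_at_peak=frac)


def fit_decay_tau(
    traces: TransientTraces,
    stimulus_index: int = -1,
    window: float = 50.0,
) -> tuple[float, dict]:
    """Fit A·exp(−(t−t_peak)/τ) + c to the cumulative trace after a stimulus.

    The fit runs from the cumulative peak inside the chosen stimulus window
    (default: the last stimulus) to the end of the recording.  Returns τ (ms)
    and diagnostics (A, c, R², residual SD).  Raises :class:`DecayFitError`
    when the fitted segment does not decay.
    """
    stims = sorted(traces.stimulus_times)
    if not stims:
        raise ValueError("traces carry no stimulus times")
    s = stims[stimulus_index]
    t, y = traces.time, traces.cumulative
    win = (t >= s) & (t < s + window)
    if not win.any():
        raise ValueError("stimulus window contains no frames")
    i_peak = np.flatnonzero(win)[np.argmax(y[win])]
    tt = t[i_peak:] - t[i_peak]
    yy = y[i_peak:]
    if len(tt) < 4:
        raise DecayFitError("too few frames after the peak to fit a decay")

    a0 = max(yy[0] - yy[-1], 1e-12)
    tau0 = max((tt[-1] - tt[0]) / 3.0, traces.time[1] - traces.time[0])

    def model(t_, a, tau, c):
        return a * np.exp(-t_ / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, tt, yy, p0=(a0, tau0, yy[-1]),
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as e:
        raise DecayFitError(f"decay fit did not converge: {e}") from e
    a, tau, c = popt
    resid = yy - model(tt, *popt)
    ss_tot = np.sum((yy - yy.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    diagnostics = {"A": float(a), "c": float(c), "r2": float(r2),
                   "residual_sd": float(resid.std()), "t_peak_ms": float(t[i_peak])}
    scale = max(np.abs(yy).max(), 1e-12)
    if a <= 1e-6 * scale or tau <= 0 or tau > 100 * (tt[-1] - tt[0] + 1):
        raise DecayFitError(f"non-decaying segment (A={a:.3g}, tau={tau:.3g}); "
                            f"diagnostics: {diagnostics}")
    return float(tau), diagnostics


def virtual_diameter(bouton_mask: np.ndarray, pixel_size: float) -> float:
    """Diameter (μm) of the circle whose area equals the bouton-mask area."""
    mask = np.asarray(bouton_mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("bouton mask is empty")
    area = n * float(pixel_size) ** 2
    return 2.0 * np.sqrt(area / np.pi)


#: Parameter pairs of the standard correlogram panel: each amplitude vs its
#: PPR; active area vs the three amplitudes; area/mean/cumulative vs the
#: pattern-statistic amplitudes.
DEFAULT_CORRELOGRAM_PAIRS = (
    ("peak1_cumulative", "ppr_cumulative"),
    ("peak1_mean", "ppr_mean"),
    ("peak1_active_area", "ppr_active_area"),
    ("peak1_active_area", "peak1_cumulative"),
    ("peak1_active_area", "peak1_mean"),
    ("peak1_active_area", "peak1_max"),
    ("peak1_active_area", "entropy_amplitude"),
    ("peak1_active_area", "nontriviality_amplitude"),
    ("peak1_mean", "entropy_amplitude"),
    ("peak1_mean", "nontriviality_amplitude"),
    ("peak1_cumulative", "entropy_amplitude"),
    ("peak1_cumulative", "nontriviality_amplitude"),
)


def correlate_parameters(
    summaries: pd.DataFrame | Sequence[TransientSummary],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlogram over per-bouton summary parameters.

    ``summaries`` is a tidy table (one row per bouton) or a sequence of
    :class:`TransientSummary`.  For each (x, y) pair present in the table the
    Pearson r and two-sided p are reported; constant columns are flagged and
    yield NaN.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([s.as_dict() for s in summaries])
    if len(summaries) < 3:
        raise ValueError("at least 3 summaries are required for a correlogram")
    if pairs is None:
        pairs = [(x, y) for x, y in DEFAULT_CORRELOGRAM_PAIRS
                 if x in summaries.columns and y in summaries.columns]
    rows = []
    for x, y in pairs:
        sub = summaries[[x, y]].apply(pd.to_numeric, errors="coerce").dropna()
        n = len(sub)
        if n < 3:
            rows.append({"x": x, "y": y, "n": n, "r": np.nan, "p": np.nan,
                         "flag": "fewer than 3 complete observations"})
            continue
        if sub[x].nunique() == 1 or sub[y].nunique() == 1:
            rows.append({"x": x, "y": y, "n": n, "r": np.nan, "p": np.nan,
                         "flag": "constant column; correlation undefined"})
            continue
        r, p = stats.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "n": n, "r": float(r), "p": float(p), "flag": ""})
    return pd.DataFrame(rows)


def longitudinal_track(
    movies: Sequence[tuple[float, FluorescenceMovie]],
    treatment_time: float,
    threshold_k: float = 3.0,
    filter_cutoff: float | None = 100.0,
) -> pd.DataFrame:
    """Track baseline fluorescence, baseline noise and response parameters
    across repeated recordings of the same bouton.

    ``movies`` is a time-ordered list of (timepoint in min, movie).  Per
    timepoint the mean baseline F and mean baseline SD over all ROI pixels
    are normalized to the first timepoint (bleaching / noise trend); the
    per-stimulus summary parameters are normalized to the mean of the
    pre-treatment (timepoint < ``treatment_time``) values.
    """
    if len(movies) < 2:
        raise ValueError("at least 2 timepoints are required")
    times = [tp for tp, _ in movies]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("timepoints must be strictly increasing")

    rows = []
    for tp, movie in movies:
        d = compute_dff(movie, threshold_k=threshold_k, filter_cutoff=filter_cutoff)
        tr = trace_parameters(d)
        summ = peak_and_ppr(tr)
        row = {
            "timepoint": tp,
            "baseline_f": float(d.baseline_mean.mean()),
            "baseline_sd": float(d.baseline_sd.mean()),
        }
        for kind in TRACE_KINDS:
            row[f"peak1_{kind}"] = float(summ.peaks[kind][0])
        rows.append(row)
    df = pd.DataFrame(rows)

    out = df.copy()
    out["baseline_f_norm"] = df["baseline_f"] / df["baseline_f"].iloc[0]
    out["baseline_sd_norm"] = df["baseline_sd"] / df["baseline_sd"].iloc[0]
    pre = df["timepoint"] < treatment_time
    if not pre.any():
        raise ValueError("no pre-treatment timepoints before treatment_time")
    for kind in TRACE_KINDS:
        ref = df.loc[pre, f"peak1_{kind}"].mean()
        out[f"peak1_{kind}_norm"] = df[f"peak1_{kind}"] / ref if ref != 0 else np.nan
    return out
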