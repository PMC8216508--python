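"""Ordinal-pattern entropy and non-triviality of 2D ΔF/F fields.

The spatial structure of a 2D field is summarised by the distribution of
rank-order patterns of 2×2 pixel neighbourhoods (stride 1, ties broken by
raster position), a 24-symbol alphabet.  Two scalars follow:

* H — Shannon entropy of the pattern distribution, normalized to [0, 1].
  Globally monotone or constant fields concentrate on one pattern (H = 0);
  i.i.d. noise visits all patterns equally (H → 1).
* C — non-triviality (statistical complexity), H × Q_JS, where Q_JS is the
  Jensen–Shannon divergence between the pattern distribution and the uniform
  distribution, normalized to [0, 1].  C vanishes both for perfectly ordered
  and for fully random fields and grows when a pattern at intermediate
  entropy carries a preferred orientation (anisotropy).

Both statistics are rank-based, hence invariant under adding a constant to
the field or scaling it by a positive factor.

Applied frame by frame to a ΔF/F movie, H(t) reads out the homogeneity and
C(t) the anisotropy of the glutamate landscape: evoked release concentrates
signal near release sites, which lowers H and raises C relative to the
pre-stimulus noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .iglu_transients import BASELINE_MS, DffMovie, trace_parameters

__all__ = [
    "PatternStats",
    "ordinal_pattern_distribution",
    "entropy",
    "nontriviality",
    "pattern_timecourse",
    "N_PATTERNS",
]

#: 2×2 cells have 4! rank-order patterns.
N_PATTERNS = 24

_LOG_N = np.log(N_PATTERNS)

# Normalization constant for the Jensen–Shannon disequilibrium: the largest
# JS divergence from the uniform distribution over N symbols (attained by a
# point mass), in nats.
_Q_MAX = -0.5 * (
    (N_PATTERNS + 1) / N_PATTERNS * np.log(N_PATTERNS + 1)
    - 2 * np.log(2 * N_PATTERNS)
    + np.log(N_PATTERNS)
)


@dataclass
class PatternStats:
    """Entropy/non-triviality timecourse with baseline-to-peak amplitudes.

    Amplitudes are signed so that the physiological response direction —
    entropy drops, non-triviality rises upon release — is positive:
    ``entropy_amplitude = H_baseline − H_peak`` and
    ``nontriviality_amplitude = C_peak − C_baseline``.
    """

    time: np.ndarray
    H: np.ndarray
    C: np.ndarray
    entropy_amplitude: float
    nontriviality_amplitude: float
    peak_frame: int
    baseline_H: float
    baseline_C: float


def _pattern_codes(image: np.ndarray) -> np.ndarray:
    """Lehmer code (0..23) of the rank ordering of every 2×2 window."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be 2D and at least 2×2")
    # window values in raster order: (0,0), (0,1), (1,0), (1,1)
    w = np.stack(
        [img[:-1, :-1], img[:-1, 1:], img[1:, :-1], img[1:, 1:]], axis=-1
    )
    # stable argsort: ties resolved by raster position
    order = np.argsort(w, axis=-1, kind="stable")
    o0, o1, o2 = order[..., 0], order[..., 1], order[..., 2]
    l1 = o1 - (o1 > o0)
    l2 = o2 - (o2 > o0).astype(np.int64) - (o2 > o1)
    return o0 * 6 + l1 * 2 + l2


def ordinal_pattern_distribution(
    image: np.ndarray, region: np.ndarray | None = None
) -> np.ndarray:
    """Normalized frequencies of the 24 rank-order patterns of 2×2 windows.

    ``region`` (optional boolean mask, same shape as ``image``) restricts the
    count to windows whose four pixels all lie inside the region.
    """
    codes = _pattern_codes(image)
    if region is not None:
        region = np.asarray(region, bool)
        if region.shape != np.shape(image):
            raise ValueError("region mask must match image shape")
        ok = (region[:-1, :-1] & region[:-1, 1:]
              & region[1:, :-1] & region[1:, 1:])
        codes = codes[ok]
    codes = np.ravel(codes)
    if codes.size == 0:
        raise ValueError("no complete 2×2 window inside the region")
    counts = np.bincount(codes, minlength=N_PATTERNS)
    return counts / counts.sum()


def _shannon(p: np.ndarray) -> float:
    """Shannon entropy in nats; 0·log 0 = 0."""
    nz = p[p > 0]
    return max(float(-(nz * np.log(nz)).sum()), 0.0)


def entropy(image: np.ndarray, region: np.ndarray | None = None) -> float:
    """Normalized pattern entropy H ∈ [0, 1]."""
    p = ordinal_pattern_distribution(image, region)
    return _shannon(p) / _LOG_N


def _js_disequilibrium(p: np.ndarray) -> float:
    u = np.full(N_PATTERNS, 1.0 / N_PATTERNS)
    js = _shannon((p + u) / 2.0) - 0.5 * _shannon(p) - 0.5 * _shannon(u)
    return float(js / _Q_MAX)


def nontriviality(image: np.ndarray, region: np.ndarray | None = None) -> float:
    """Non-triviality C = H · Q_JS ≥ 0 (0 for both ordered and random fields)."""
    p = ordinal_pattern_distribution(image, region)
    h = _shannon(p) / _LOG_N
    return h * _js_disequilibrium(p)


def pattern_timecourse(
    dff: DffMovie,
    analysis_region: np.ndarray | None = None,
    margin: int = 2,
    window: float = 50.0,
) -> PatternStats:
    """H(t) and C(t) of the ΔF/F field over the (dilated) bouton region.

    The analysis region defaults to the bouton mask dilated by ``margin``
    pixels (the readout deliberately includes a small rim of surrounding
    space).  Frames are analyzed on the region's bounding box with windows
    touching outside-region pixels excluded.  Amplitudes compare the mean
    over the 50-ms pre-stimulus baseline with the value at the frame of peak
    cumulative response after the first stimulus.
    """
    if analysis_region is None:
        region = binary_dilation(dff.bouton_mask, iterations=margin)
    else:
        region = np.asarray(analysis_region, bool)
        if region.shape != dff.bouton_mask.shape:
            raise ValueError("analysis_region must match the frame shape")
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    sub_region = region[sl]

    n_frames = dff.dff.shape[0]
    H = np.empty(n_frames)
    C = np.empty(n_frames)
    for f in range(n_frames):
        p = ordinal_pattern_distribution(dff.dff[f][sl], sub_region)
        h = _shannon(p) / _LOG_N
        H[f] = h
        C[f] = h * _js_disequilibrium(p)

    t = dff.time
    if not dff.stimulus_times:
        raise ValueError("dff carries no stimulus times")
    first = min(dff.stimulus_times)
    base = (t >= first - BASELINE_MS) & (t < first)
    traces = trace_parameters(dff)
    win = (t >= first) & (t < first + window)
    idx = np.flatnonzero(win)
    peak_frame = int(idx[np.argmax(traces.cumulative[win])])

    h_base = float(H[base].mean())
    c_base = float(C[base].mean())
    return PatternStats(
        time=t,
        H=H,
        C=C,
        entropy_amplitude=h_base - float(H[peak_frame]),
        nontriviality_amplitude=float(C[peak_frame]) - c_base,
        peak_frame=peak_frame,
        baseline_H=h_base,
        baseline_C=c_base,
    )
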