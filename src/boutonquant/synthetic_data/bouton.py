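"""Forward model for single-bouton glutamate-sensor movies.

The simulated bouton carries discrete release sites inside a circular mask.
Each electrical stimulus triggers release at each site independently with
``site_release_prob``.  A release event deposits glutamate that spreads as an
isotropic in-plane Gaussian (σ = ``spatial_sigma``, truncated at 3σ so the
ground-truth active footprint is a well-defined pixel set) and follows a
linear rise (``rise_time``) / monoexponential decay (``decay_tau``) time
course.  The saturating sensor converts concentration to
ΔF/F = dff_max · [Glu]/([Glu] + Kd); fluorescence is
baseline_f · (1 + ΔF/F/100) · bleach(t) + Gaussian noise.

Per-site release probabilities and quantal cleft concentrations are not
known for mossy fiber boutons; the defaults here are placeholders chosen to
put single-pulse responses in the lower part of the sensor's working range
(concentration below Kd), and every quantity is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..iglu_transients import FluorescenceMovie

__all__ = ["BoutonSimConfig", "BoutonGroundTruth", "simulate_bouton_movie"]

#: Radius (in σ) at which the spatial glutamate footprint is truncated.
FOOTPRINT_SIGMAS = 3.0


@dataclass
class BoutonSimConfig:
    """Study conditions for one simulated bouton recording.

    Times in ms, lengths in μm, concentrations in μM, ΔF/F in %.
    """

    roi_shape: tuple[int, int] = (13, 13)       # 169-pixel high-speed ROI
    pixel_size: float = 0.2                     # μm/pixel
    frame_rate: float = 1600.0                  # Hz
    duration: float = 250.0                     # ms
    stimulus_times: tuple[float, ...] = (60.0, 110.0)  # 50-ms paired pulses
    n_release_sites: int = 4
    site_release_prob: float = 0.5
    quanta_per_release: int = 1
    glut_peak_conc: float = 300.0               # μM per quantum at the site
    spatial_sigma: float = 0.25                 # μm in-plane spread
    sensor_kd: float = 600.0                    # μM
    dff_max: float = 100.0                      # % at saturation
    decay_tau: float = 15.0                     # ms
    rise_time: float = 1.0                      # ms
    baseline_f: float = 100.0                   # a.u.
    noise_sd: float = 2.0                       # a.u.
    bleach_tau: float | None = None             # ms; None = no bleaching
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.site_release_prob <= 1.0:
            raise ValueError("site_release_prob must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if any(t < 0 for t in self.stimulus_times):
            raise ValueError("stimulus times must be >= 0")
        if self.stimulus_times:
            need = max(self.stimulus_times) + 3 * self.decay_tau
            if self.duration < need:
                raise ValueError(
                    f"duration {self.duration:g} ms is shorter than last "
                    f"stimulus + 3·decay_tau = {need:g} ms"
                )
        if min(self.roi_shape) < 3:
            raise ValueError("roi_shape must be at least 3×3")
        for name in ("pixel_size", "duration", "decay_tau", "rise_time",
                     "sensor_kd", "dff_max", "spatial_sigma", "baseline_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.glut_peak_conc < 0:
            raise ValueError("noise_sd and glut_peak_conc must be >= 0")


@dataclass
class BoutonGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    site_positions: np.ndarray          # (n_sites, 2) pixel (row, col)
    release_events: np.ndarray          # (n_sites, n_stimuli) bool
    true_active_mask: np.ndarray        # (n_stimuli, rows, cols) bool
    true_decay_tau: float
    bouton_mask: np.ndarray = field(default=None)
    noise_free_dff: np.ndarray = field(default=None)  # (frames, rows, cols) %


def _circular_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rad = min(rows, cols) / 2.0 - 0.5
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2


def _temporal_kernel(t: np.ndarray, rise: float, tau: float) -> np.ndarray:
    """Linear rise to 1 over ``rise`` ms, then exp(−(t − rise)/tau); 0 for t<0."""
    k = np.zeros_like(t)
    up = (t >= 0) & (t < rise)
    k[up] = t[up] / rise
    down = t >= rise
    k[down] = np.exp(-(t[down] - rise) / tau)
    return k


def simulate_bouton_movie(
    config: BoutonSimConfig,
) -> tuple[FluorescenceMovie, BoutonGroundTruth]:
    """Simulate one paired-pulse recording of a single bouton.

    Returns the raw movie and the generating ground truth (site positions,
    per-stimulus release events, per-stimulus active-pixel footprint, and the
    noise-free ΔF/F field for oracle comparisons).
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.roi_shape
    frame_interval = 1000.0 / config.frame_rate
    n_frames = int(round(config.duration / frame_interval))
    t = np.arange(n_frames) * frame_interval

    mask = _circular_mask(config.roi_shape)
    inside = np.argwhere(mask)
    # keep sites off the mask rim so their 3σ footprint stays mostly on the ROI
    centre = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    rad = min(rows, cols) / 2.0 - 0.5
    core = inside[np.linalg.norm(inside - centre, axis=1) <= max(rad - 1.5, 1.0)]
    idx = rng.choice(len(core), size=config.n_release_sites,
                     replace=config.n_release_sites > len(core))
    sites = core[idx].astype(float)

    stims = np.asarray(config.stimulus_times, dtype=float)
    events = rng.random((config.n_release_sites, len(stims))) < config.site_release_prob

    # spatial footprint per site: Gaussian truncated at FOOTPRINT_SIGMAS·σ
    sigma_px = config.spatial_sigma / config.pixel_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    footprints = []
    for (sr, sc) in sites:
        d2 = (rr - sr) ** 2 + (cc - sc) ** 2
        w = np.exp(-d2 / (2 * sigma_px**2))
        w[d2 > (FOOTPRINT_SIGMAS * sigma_px) ** 2] = 0.0
        footprints.append(w)
    footprints = np.array(footprints)  # (n_sites, rows, cols)

    amp = config.glut_peak_conc * config.quanta_per_release
    conc = np.zeros((n_frames, rows, cols))
    for j, s in enumerate(stims):
        kern = _temporal_kernel(t - s, config.rise_time, config.decay_tau)
        active_sites = np.flatnonzero(events[:, j])
        if active_sites.size:
            spatial = footprints[active_sites].sum(axis=0)
            conc += amp * kern[:, None, None] * spatial[None, :, :]

    dff = config.dff_max * conc / (conc + config.sensor_kd)  # %
    bleach = (np.exp(-t / config.bleach_tau) if config.bleach_tau
              else np.ones_like(t))
    f = config.baseline_f * (1.0 + dff / 100.0) * bleach[:, None, None]
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, size=f.shape)

    # Glutamate decays exponentially and never reaches zero, so the set of
    # pixels with nonzero concentration during stimulus window j is the union
    # of the footprints of every site that released at any stimulus <= j.
    true_active = np.zeros((len(stims), rows, cols), dtype=bool)
    for j in range(len(stims)):
        act = np.flatnonzero(events[:, : j + 1].any(axis=1))
        if act.size:
            true_active[j] = footprints[act].sum(axis=0) > 0

    movie = FluorescenceMovie(
        data=f,
        frame_interval=frame_interval,
        pixel_size=config.pixel_size,
        stimulus_times=tuple(stims),
        bouton_mask=mask,
        condition_label="synthetic",
    )
    truth = BoutonGroundTruth(
        site_positions=sites,
        release_events=events,
        true_active_mask=true_active,
        true_decay_tau=config.decay_tau,
        bouton_mask=mask,
        noise_free_dff=dff,
    )
    return movie, truth
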