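"""Synthetic three-channel super-resolution fields of synapse triads.

Each triad places a calcium-channel (Cav2.1) and a release-site (Munc13-1)
point source separated by a draw from a configurable distance distribution
(random in-plane orientation), plus a postsynaptic (Homer1) source displaced
``homer_offset`` nm from the pair midpoint perpendicular to the pair axis
(the cleft is trans-synaptic).  Channels are blurred with the 2D Lorentzian
PSF of the imaging model, Poisson shot noise plus Gaussian read noise is
applied, and per-channel distractor spots emulate out-of-triad clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sted_coupling import StedField

__all__ = ["StedSimConfig", "TriadTruth", "simulate_sted_field",
           "draw_separations", "truncnorm_mu_for_mean"]


@dataclass
class StedSimConfig:
    """Study conditions for one simulated STED field (lengths in nm)."""

    field_size: tuple[int, int] = (500, 500)   # pixels
    pixel_size: float = 20.0                   # nm
    n_triads: int = 12
    # named family + parameters: ("delta", d), ("truncnorm", mu, sigma),
    # ("uniform", lo, hi)
    separation_distribution: tuple = ("truncnorm", 64.6, 35.0)
    homer_offset: float = 90.0                 # nm, trans-synaptic
    psf_fwhm: float = 40.0                     # nm
    spot_amplitude: float = 1000.0             # expected peak counts
    poisson_noise: bool = True
    read_noise_sd: float = 5.0                 # counts
    n_distractors: int = 10                    # per channel
    triad_min_sep: float = 600.0               # nm between triad centres
    distractor_clearance: float = 300.0        # nm from same-channel spots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be positive")
        if self.n_triads < 0 or self.n_distractors < 0:
            raise ValueError("counts must be >= 0")
        fam = self.separation_distribution[0]
        if fam not in ("delta", "truncnorm", "uniform"):
            raise ValueError(f"unknown separation family {fam!r}")
        if fam == "delta" and self.separation_distribution[1] < 0:
            raise ValueError("separation must be >= 0")
        if fam == "uniform" and self.separation_distribution[1] < 0:
            raise ValueError("separation lower bound must be >= 0")


@dataclass
class TriadTruth:
    """Ground-truth triad geometry in pixel coordinates (row, col)."""

    cav: tuple[float, float]
    munc: tuple[float, float]
    homer: tuple[float, float]
    separation_nm: float


def truncnorm_mu_for_mean(target_mean: float, sigma: float) -> float:
    """Pre-truncation μ such that the zero-truncated normal has the target
    mean.

    Truncation at zero lifts the mean by σ·φ(μ/σ)/Φ(μ/σ), and the lift
    differs between conditions, so studies that need a prescribed *mean*
    separation (or a prescribed mean shift between groups) must invert it.
    """
    from scipy import optimize, stats

    def trunc_mean(mu):
        return stats.truncnorm(-mu / sigma, np.inf, loc=mu,
                               scale=sigma).mean()

    lo = target_mean - 5 * sigma
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean,
                                 lo, target_mean))


def draw_separations(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n separations (nm) from a named distribution family.

    ``truncnorm`` redraws negative normal deviates (truncation at 0).
    """
    fam = dist[0]
    if fam == "delta":
        return np.full(n, float(dist[1]))
    if fam == "uniform":
        lo, hi = dist[1], dist[2]
        return rng.uniform(lo, hi, size=n)
    if fam == "truncnorm":
        mu, sigma = dist[1], dist[2]
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            draw = rng.normal(mu, sigma, size=todo.size)
            ok = draw >= 0
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out
    raise ValueError(f"unknown separation family {fam!r}")


def _render_spots(shape, positions, amplitudes, fwhm_nm, pixel_size_nm,
                  truncate_fwhm=10.0):
    """Accumulate Lorentzian-blurred point sources at continuous positions.

    The PSF is evaluated analytically at each pixel center relative to the
    continuous (sub-pixel) source position, so the rendered peak sits exactly
    at the ground-truth coordinate; amplitudes are peak counts.  Support is
    truncated at ``truncate_fwhm`` × FWHM, matching the deconvolution kernel.
    """
    img = np.zeros(shape)
    half = int(np.ceil(truncate_fwhm * fwhm_nm / pixel_size_nm))
    for (r, c), a in zip(positions, amplitudes):
        ri, ci = int(np.round(r)), int(np.round(c))
        r0, r1 = max(ri - half, 0), min(ri + half + 1, shape[0])
        c0, c1 = max(ci - half, 0), min(ci + half + 1, shape[1])
        rr = (np.arange(r0, r1) - r) * pixel_size_nm
        cc = (np.arange(c0, c1) - c) * pixel_size_nm
        r2 = rr[:, None] ** 2 + cc[None, :] ** 2
        img[r0:r1, c0:c1] += a / (1.0 + 4.0 * r2 / fwhm_nm**2)
    return img


def simulate_sted_field(
    config: StedSimConfig,
) -> tuple[StedField, list[TriadTruth]]:
    """Simulate one three-channel field; returns the field and true triads."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_size
    px = config.pixel_size

    # margin keeps every triad member inside the field
    margin_nm = max(config.homer_offset, 250.0) + 3 * config.psf_fwhm
    margin = margin_nm / px
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise ValueError("field too small for the requested margins")

    seps = draw_separations(config.separation_distribution, config.n_triads, rng)
    truths: list[TriadTruth] = []
    cav_pos, munc_pos, homer_pos = [], [], []
    centres: list[np.ndarray] = []
    min_sep_px = config.triad_min_sep / px
    for d in seps:
        for _ in range(1000):
            centre = np.array([rng.uniform(margin, rows - margin),
                               rng.uniform(margin, cols - margin)])
            if centres and min(np.linalg.norm(centre - c) for c in centres) \
                    < min_sep_px:
                continue
            theta = rng.uniform(0.0, 2 * np.pi)
            axis = np.array([np.sin(theta), np.cos(theta)])
            perp = np.array([-axis[1], axis[0]])
            half = (d / 2.0) / px
            cav = centre - half * axis
            munc = centre + half * axis
            homer = centre + (config.homer_offset / px) * perp
            pts = np.array([cav, munc, homer])
            if ((pts[:, 0] > 1) & (pts[:, 0] < rows - 2)
                    & (pts[:, 1] > 1) & (pts[:, 1] < cols - 2)).all():
                break
        else:
            raise RuntimeError(
                "could not place triad inside the field; reduce n_triads or "
                "triad_min_sep")
        centres.append(centre)
        cav_pos.append(cav)
        munc_pos.append(munc)
        homer_pos.append(homer)
        truths.append(TriadTruth(cav=tuple(cav), munc=tuple(munc),
                                 homer=tuple(homer), separation_nm=float(d)))

    channels = {}
    for name, pos in (("cav", cav_pos), ("munc", munc_pos),
                      ("homer", homer_pos)):
        pos = list(pos)
        amps = [config.spot_amplitude * rng.uniform(0.7, 1.3) for _ in pos]
        clearance_px = config.distractor_clearance / px
        for _ in range(config.n_distractors):
            for _ in range(200):
                cand = np.array([rng.uniform(2, rows - 3),
                                 rng.uniform(2, cols - 3)])
                if not pos or min(np.linalg.norm(cand - p) for p in pos) \
                        >= clearance_px:
                    break
            pos.append(cand)
            amps.append(config.spot_amplitude * rng.uniform(0.3, 1.0))
        img = _render_spots((rows, cols), pos, amps, config.psf_fwhm, px)
        if config.poisson_noise:
            img = rng.poisson(img).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        channels[name] = np.maximum(img, 0.0)

    field = StedField(channels=channels, pixel_size=px,
                      condition="synthetic")
    return field, truths
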