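"""Synthetic serial-section bouton reconstructions with known ground truth.

A bouton is a stack of identical rough-boundary polygonal profiles (one per
70-nm section).  Active zones are arcs of the membrane traced over one or
more contiguous sections and sharing an az_id.  Vesicles come in three
populations: docked (center at one radius from an AZ trace → membrane
contact), tethered (center within the tether shell of an AZ trace), and free
vesicles drawn from a configurable point process — uniform in the stack, or
a parent–offspring (Thomas) cluster process — under a hard-core pairwise
constraint.  Free vesicles keep an exclusion margin beyond the tether
cutoff from every AZ trace so that the docked/tethered ground truth is
exactly the set the classifier should recover (a deliberate idealization of
real micrographs, where the populations grade into each other).
Mitochondria are concentric scaled copies of the membrane profile occupying
an exact area (hence volume) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from ..em_morphometry import Reconstruction, Section

__all__ = ["EmSimConfig", "EmGroundTruth", "simulate_reconstruction"]

#: Free vesicles stay this far (nm) beyond the tether cutoff from AZ traces.
AZ_EXCLUSION_MARGIN = 10.0

#: Docked/tethered placement treats this as the tether shell outer bound (nm).
TETHER_MAX = 60.0


@dataclass
class EmSimConfig:
    """Study conditions for one simulated reconstruction (lengths in nm)."""

    n_sections: int = 8
    section_thickness: float = 70.0
    bouton_area_um2: float = 4.0          # per-profile area
    boundary_roughness: float = 0.08      # relative radial modulation
    n_azs: int = 4
    az_length_mean: float = 400.0         # nm per section trace
    az_sections: int = 3                  # contiguous sections per AZ
    vesicle_count: int = 120              # free vesicles
    vesicle_diameter: float = 40.0
    clustering: str = "uniform"           # "uniform" | "thomas"
    parent_intensity: float = 2.0         # parents per reconstruction (thomas)
    offspring_sd: float = 60.0            # nm (thomas)
    hardcore_radius: float = 40.0         # min center-center distance
    docked_per_az: int = 3                # per section the AZ spans (3×3 ≈ 9/AZ)
    tethered_per_az: int = 1              # per section the AZ spans
    mito_volume_fraction: float = 15.0    # %
    max_attempts: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if self.clustering not in ("uniform", "thomas"):
            raise ValueError(f"unknown clustering {self.clustering!r}")
        if not 0 <= self.mito_volume_fraction < 100:
            raise ValueError("mito_volume_fraction must be in [0, 100)")
        if self.vesicle_count < 0 or self.n_azs < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class EmGroundTruth:
    """Counts, geometry and process parameters behind a reconstruction."""

    volume_um3: float
    profile_area_um2: float
    az_count: int
    az_areas_um2: dict
    sv_count: int                  # all vesicles (free + docked + tethered)
    free_count: int
    docked_count: int
    tethered_count: int
    sv_density_um3: float
    mito_fraction_pct: float
    clustering: str
    hardcore_radius_nm: float
    vesicle_xyz_nm: np.ndarray


def _rough_profile(area_nm2: float, roughness: float,
                   rng: np.random.Generator, n_vertices: int = 64) -> Polygon:
    """Closed rough-boundary profile with low-order harmonic modulation."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 6):
        r += (roughness / k) * rng.normal() * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None)
    base = np.sqrt(area_nm2 / np.pi)
    poly = Polygon(np.column_stack([base * r * np.cos(theta),
                                    base * r * np.sin(theta)]))
    # rescale so the polygon area matches the request exactly
    scale = np.sqrt(area_nm2 / poly.area)
    pts = np.asarray(poly.exterior.coords)[:-1] * scale
    return Polygon(pts)


def _inward_point(boundary: LineString, poly: Polygon, s: float,
                  depth: float) -> np.ndarray:
    """Point ``depth`` nm inside the membrane at arc position ``s``."""
    p = boundary.interpolate(s)
    eps = max(boundary.length * 1e-4, 1.0)
    q = boundary.interpolate((s + eps) % boundary.length)
    tangent = np.array([q.x - p.x, q.y - p.y])
    tangent /= np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])
    cand = np.array([p.x, p.y]) + depth * normal
    if not poly.contains(Point(cand)):
        cand = np.array([p.x, p.y]) - depth * normal
    return cand


def simulate_reconstruction(
    config: EmSimConfig,
) -> tuple[Reconstruction, EmGroundTruth]:
    """Generate a reconstruction plus its exact ground truth."""
    rng = np.random.default_rng(config.seed)
    area_nm2 = config.bouton_area_um2 * 1e6
    profile = _rough_profile(area_nm2, config.boundary_roughness, rng)
    boundary = LineString(list(profile.exterior.coords))
    r_ves = config.vesicle_diameter / 2.0
    thick = config.section_thickness
    nz = config.n_sections

    # --- active zones: membrane arcs over contiguous sections, shared az_id
    az_by_section: dict[int, list] = {z: [] for z in range(nz)}
    az_lines_by_section: dict[int, list] = {z: [] for z in range(nz)}
    az_areas: dict[int, float] = {}
    for aid in range(config.n_azs):
        length = max(rng.normal(config.az_length_mean,
                                0.2 * config.az_length_mean), 50.0)
        start = rng.uniform(0.0, boundary.length)
        nsec = min(config.az_sections, nz)
        z0 = rng.integers(0, nz - nsec + 1)
        total = 0.0
        for z in range(z0, z0 + nsec):
            end = start + length
            if end <= boundary.length:
                seg = substring(boundary, start, end)
            else:  # wrap around the closed boundary
                seg1 = substring(boundary, start, boundary.length)
                seg2 = substring(boundary, 0.0, end - boundary.length)
                seg = LineString(list(seg1.coords) + list(seg2.coords)[1:])
            pts = np.asarray(seg.coords)
            az_by_section[z].append({"az_id": aid, "points": pts.tolist()})
            az_lines_by_section[z].append((aid, LineString(pts), start, length))
            total += seg.length * thick
        az_areas[aid] = total / 1e6  # μm²

    # --- docked and tethered vesicles at the AZs
    placed: list[tuple[float, float, int]] = []   # (x, y, z_index)
    ves_by_section: dict[int, list] = {z: [] for z in range(nz)}
    hc2 = config.hardcore_radius**2

    def hardcore_ok(x, y, z):
        for (px, py, pz) in placed:
            dz = (z - pz) * thick
            if (x - px) ** 2 + (y - py) ** 2 + dz * dz < hc2:
                return False
        return True

    def place(x, y, z):
        placed.append((x, y, z))
        ves_by_section[z].append({"x": float(x), "y": float(y), "r": r_ves})

    n_docked = n_teth = 0
    for z in range(nz):
        for (aid, line, start, length) in az_lines_by_section[z]:
            for kind, count in (("docked", config.docked_per_az),
                                ("tethered", config.tethered_per_az)):
                done = 0
                for _ in range(config.max_attempts):
                    if done >= count:
                        break
                    s = rng.uniform(0.05, 0.95) * line.length
                    if kind == "docked":
                        depth = r_ves          # membrane contact: gap = 0
                    else:
                        depth = rng.uniform(r_ves + 5.0, TETHER_MAX - 1.0)
                    cand = _inward_point(line, profile, s, depth)
                    if not profile.contains(Point(cand)):
                        continue
                    if not hardcore_ok(cand[0], cand[1], z):
                        continue
                    place(cand[0], cand[1], z)
                    done += 1
                if done < count:
                    raise RuntimeError(
                        f"could not place {count} {kind} vesicles at AZ {aid} "
                        f"within {config.max_attempts} attempts "
                        "(hard-core constraint infeasible)")
                if kind == "docked":
                    n_docked += done
                else:
                    n_teth += done

    # --- free vesicles: uniform or Thomas process, AZ-exclusion + hard-core
    minx, miny, maxx, maxy = profile.bounds
    exclusion = TETHER_MAX + r_ves + AZ_EXCLUSION_MARGIN

    def free_ok(x, y, z):
        if not profile.contains(Point(x, y)):
            return False
        for (_, line, _, _) in az_lines_by_section[z]:
            if line.distance(Point(x, y)) < exclusion:
                return False
        return hardcore_ok(x, y, z)

    if config.clustering == "thomas":
        n_parents = max(int(round(config.parent_intensity)), 1)
        parents = []
        for _ in range(n_parents):
            for _ in range(config.max_attempts):
                px = rng.uniform(minx, maxx)
                py = rng.uniform(miny, maxy)
                pz = rng.uniform(-0.5, nz - 0.5)
                if profile.contains(Point(px, py)):
                    parents.append((px, py, pz))
                    break
        parents = np.asarray(parents)

    n_free = 0
    attempts = 0
    while n_free < config.vesicle_count:
        attempts += 1
        if attempts > config.max_attempts:
            raise RuntimeError(
                f"requested vesicle_count={config.vesicle_count} infeasible "
                f"under hard-core radius {config.hardcore_radius} nm within "
                f"{config.max_attempts} attempts")
        if config.clustering == "uniform":
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            z = int(rng.integers(0, nz))
        else:
            p = parents[rng.integers(0, len(parents))]
            x = p[0] + rng.normal(0.0, config.offspring_sd)
            y = p[1] + rng.normal(0.0, config.offspring_sd)
            zc = p[2] + rng.normal(0.0, config.offspring_sd) / thick
            z = int(np.clip(np.round(zc), 0, nz - 1))
        if free_ok(x, y, z):
            place(x, y, z)
            n_free += 1

    # --- mitochondria: concentric scaled profile with exact area fraction
    mito_by_section: dict[int, list] = {z: [] for z in range(nz)}
    if config.mito_volume_fraction > 0:
        scale = np.sqrt(config.mito_volume_fraction / 100.0)
        centroid = np.array([profile.centroid.x, profile.centroid.y])
        pts = np.asarray(profile.exterior.coords)[:-1]
        mito_poly = (centroid + (pts - centroid) * scale).tolist()
        for z in range(nz):
            mito_by_section[z].append(mito_poly)

    coords = np.asarray(profile.exterior.coords)[:-1].tolist()
    sections = [
        Section(z_index=z, presyn=[coords], az=az_by_section[z],
                mito=mito_by_section[z], vesicles=ves_by_section[z])
        for z in range(nz)
    ]
    rec = Reconstruction(section_thickness=thick, sections=sections,
                         bouton_id="synthetic", condition="synthetic")

    volume = profile.area * thick * nz / 1e9
    xyz = np.array([(x, y, z * thick) for (x, y, z) in placed], float)
    truth = EmGroundTruth(
        volume_um3=volume,
        profile_area_um2=profile.area / 1e6,
        az_count=config.n_azs,
        az_areas_um2=az_areas,
        sv_count=len(placed),
        free_count=n_free,
        docked_count=n_docked,
        tethered_count=n_teth,
        sv_density_um3=len(placed) / volume,
        mito_fraction_pct=config.mito_volume_fraction,
        clustering=config.clustering,
        hardcore_radius_nm=config.hardcore_radius,
        vesicle_xyz_nm=xyz,
    )
    return rec, truth
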