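"""Seeded synthetic data with the statistical structure of micropatterned
cell islands.

Two generators stand in for the microscopy inputs:

* :func:`generate_cell_table` — per-cell tables of ~600 µm circular islands
  with spatially uniform cell density and marker positivity following a
  logistic curve in dimensionless radius (rising for biliary-like markers,
  falling for hepatocytic-like ones), plus lognormal immunolabel
  intensities conditioned on positivity.
* :func:`generate_displacement_data` — a ring-shaped traction field peaking
  near the island periphery, its exact Boussinesq surface displacements,
  bead-localisation noise, and (optionally) rendered bead images.

Every generator is a pure function of its config (which carries the seed),
and emits the ground-truth parameters alongside the data so downstream
recovery can be tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lattice import HexLattice
from .tfm import DisplacementField, TractionField, forward_displacement

__all__ = [
    "LogisticMarkerModel",
    "IslandSimConfig",
    "TractionSimConfig",
    "generate_cell_table",
    "generate_displacement_data",
    "generate_stress_gradient_truth",
    "MARKER_PRESETS",
]


@dataclass(frozen=True)
class LogisticMarkerModel:
    """Marker positivity probability as a logistic function of R.

    P(positive | R) = p_min + (p_max − p_min) / (1 + exp(−k (R − r0)))

    ``k > 0`` rises toward the periphery (biliary-like), ``k < 0`` falls
    (hepatocytic-like), ``k = 0`` is flat at the midpoint.
    ``intensity_pos``/``intensity_neg`` are lognormal (mean, sigma) pairs of
    the underlying normal for the immunolabel intensity in positive and
    negative cells.
    """

    p_min: float = 0.05
    p_max: float = 0.8
    k: float = 12.0
    r0: float = 0.85
    intensity_pos: tuple[float, float] = (5.0, 0.4)  # lognormal mu, sigma
    intensity_neg: tuple[float, float] = (3.0, 0.4)

    def __post_init__(self) -> None:
        if not (0 <= self.p_min <= 1 and 0 <= self.p_max <= 1):
            raise ValueError("positivity probabilities must be in [0, 1]")

    def probability(self, R: np.ndarray, p_max_shift: float = 0.0) -> np.ndarray:
        p_max = np.clip(self.p_max + p_max_shift, 0.0, 1.0)
        return self.p_min + (p_max - self.p_min) / (1.0 + np.exp(-self.k * (np.asarray(R) - self.r0)))


# presets emulating the headline spatial phenotypes; effect sizes are
# synthetic choices, not measured values
MARKER_PRESETS: dict[str, LogisticMarkerModel] = {
    "OPN-like": LogisticMarkerModel(p_min=0.05, p_max=0.8, k=12.0, r0=0.85),
    "ALB-like": LogisticMarkerModel(p_min=0.1, p_max=0.55, k=-8.0, r0=0.6),
    "DECMA-uniform": LogisticMarkerModel(p_min=0.45, p_max=0.45, k=0.0, r0=0.5),
}


@dataclass
class IslandSimConfig:
    """Study design for a synthetic cell-table experiment.

    ``condition_effects`` maps condition labels (e.g. arrayed ligand) to an
    additive shift of each marker's peak positivity ``p_max``; the reference
    level has shift 0.  ``n_islands`` islands are generated *per level*.
    """

    n_islands: int = 18
    cells_per_island: float = 600.0
    cells_dispersion: float = 0.0  # Poisson when 0; gamma-mixed otherwise
    island_radius: float = 300.0  # µm
    markers: dict = field(default_factory=lambda: {"OPN": MARKER_PRESETS["OPN-like"],
                                                   "ALB": MARKER_PRESETS["ALB-like"]})
    condition_effects: dict = field(default_factory=lambda: {"IgG": 0.0})
    condition_name: str = "ligand"
    seed: int = 0


def generate_cell_table(
    config: IslandSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sample per-cell positions, positivity and intensities for all islands.

    Returns ``(cells, islands, truth)`` where ``cells`` has columns
    ``cell_id, island_id, <condition>, x, y`` plus per-marker
    ``<m>_intensity`` / ``<m>_positive``; ``islands`` has
    ``island_id, centroid_x, centroid_y, effective_radius, <condition>``;
    and ``truth`` records the generating parameters.

    Positions are uniform in the disc (area-correct ``r = R√u`` sampling);
    positivity is Bernoulli with the logistic-in-R probability shifted per
    condition level.
    """
    rng = np.random.default_rng(config.seed)
    cells_rows = []
    island_rows = []
    island_id = 0
    for level, shift in config.condition_effects.items():
        for _ in range(config.n_islands):
            cx, cy = rng.uniform(0, 5000, size=2)
            if config.cells_dispersion > 0:
                lam = config.cells_per_island * rng.gamma(
                    1.0 / config.cells_dispersion, config.cells_dispersion
                )
            else:
                lam = config.cells_per_island
            n = rng.poisson(lam)
            radii = config.island_radius * np.sqrt(rng.uniform(size=n))
            theta = rng.uniform(0, 2 * np.pi, size=n)
            x = cx + radii * np.cos(theta)
            y = cy + radii * np.sin(theta)
            R = radii / config.island_radius
            row = {
                "cell_id": np.arange(n),
                "island_id": island_id,
                config.condition_name: level,
                "x": x,
                "y": y,
            }
            for name, model in config.markers.items():
                p = model.probability(R, p_max_shift=shift)
                if np.any((p < 0) | (p > 1)):
                    raise ValueError(f"invalid positivity probability for marker {name}")
                pos = rng.uniform(size=n) < p
                mu_p, sg_p = model.intensity_pos
                mu_n, sg_n = model.intensity_neg
                inten = np.where(
                    pos,
                    rng.lognormal(mu_p, sg_p, size=n),
                    rng.lognormal(mu_n, sg_n, size=n),
                )
                row[f"{name}_positive"] = pos
                row[f"{name}_intensity"] = inten
            cells_rows.append(pd.DataFrame(row))
            island_rows.append(
                {
                    "island_id": island_id,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "effective_radius": config.island_radius,
                    config.condition_name: level,
                }
            )
            island_id += 1
    cells = pd.concat(cells_rows, ignore_index=True)
    islands = pd.DataFrame(island_rows)
    truth = {
        "seed": config.seed,
        "condition_effects": dict(config.condition_effects),
        "markers": {k: asdict(v) for k, v in config.markers.items()},
        "island_radius": config.island_radius,
        "cells_per_island": config.cells_per_island,
    }
    return cells, islands, truth


@dataclass
class TractionSimConfig:
    """Ground-truth ring traction field and its measurement noise."""

    peak_magnitude: float = 100.0  # Pa
    peak_radius_frac: float = 0.9  # of island radius
    ring_width: float = 30.0  # µm (Gaussian sigma)
    island_radius: float = 300.0  # µm
    grid_spacing: float = 10.0  # µm
    field_size: float = 1000.0  # µm
    noise_px: float = 0.05  # bead-localisation sigma, px
    pixel_size: float = 0.65  # µm/px
    bead_density: float = 0.02  # beads per µm² (image rendering)
    substrate_E: float = 30000.0  # Pa
    substrate_nu: float = 0.48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_magnitude < 0:
            raise ValueError("peak_magnitude must be >= 0")
        if not (0 < self.peak_radius_frac <= 1):
            raise ValueError("peak_radius_frac must be in (0, 1]")


def _ring_traction(config: TractionSimConfig) -> TractionField:
    n = int(round(config.field_size / config.grid_spacing))
    ax = (np.arange(n) - (n - 1) / 2.0) * config.grid_spacing
    gx, gy = np.meshgrid(ax, ax)
    cx = cy = 0.0
    dx, dy = gx - cx, gy - cy
    r = np.hypot(dx, dy)
    r_peak = config.peak_radius_frac * config.island_radius
    mag = config.peak_magnitude * np.exp(-0.5 * ((r - r_peak) / config.ring_width) ** 2)
    mag[r > config.island_radius * 1.05] = 0.0  # tractions only under the island
    with np.errstate(invalid="ignore"):
        ux, uy = np.where(r > 0, dx / np.maximum(r, 1e-12), 0.0), np.where(
            r > 0, dy / np.maximum(r, 1e-12), 0.0
        )
    # centripetal: cells pull the gel inward
    return TractionField(
        grid_x=gx, grid_y=gy, t_x=-mag * ux, t_y=-mag * uy,
        substrate_E=config.substrate_E, substrate_nu=config.substrate_nu,
        regularization=0.0,
    )


def generate_displacement_data(
    config: TractionSimConfig,
    render_beads: bool = False,
) -> dict:
    """Ground-truth traction + noisy displacement (+ optional bead images).

    Returns a dict with keys ``traction`` (ground-truth
    :class:`~islandfate.tfm.TractionField`), ``displacement`` (noisy
    :class:`~islandfate.tfm.DisplacementField`),
    ``displacement_clean``, ``truth`` (parameter record) and, when
    ``render_beads``, a :class:`~islandfate.tfm.BeadImagePair`.
    """
    rng = np.random.default_rng(config.seed)
    truth_field = _ring_traction(config)
    clean = forward_displacement(truth_field)
    peak_disp = float(np.hypot(clean.u, clean.v).max())
    if peak_disp > 0.1 * config.island_radius:
        import warnings

        warnings.warn(
            "peak displacement exceeds 10% of the island radius; "
            "linear half-space theory is questionable at this load"
        )
    sigma_um = config.noise_px * config.pixel_size
    noisy = DisplacementField(
        grid_x=clean.grid_x,
        grid_y=clean.grid_y,
        u=clean.u + rng.normal(0.0, sigma_um, clean.u.shape),
        v=clean.v + rng.normal(0.0, sigma_um, clean.v.shape),
    )
    out = {
        "traction": truth_field,
        "displacement": noisy,
        "displacement_clean": clean,
        "truth": {
            "peak_magnitude": config.peak_magnitude,
            "peak_radius_um": config.peak_radius_frac * config.island_radius,
            "peak_radius_frac": config.peak_radius_frac,
            "ring_width": config.ring_width,
            "noise_um": sigma_um,
            "seed": config.seed,
        },
    }
    if render_beads:
        out["beads"] = _render_bead_pair(config, clean, rng)
    return out


def _render_bead_pair(config: TractionSimConfig, disp: DisplacementField, rng):
    """Gaussian-spot bead images before/after warping by the displacement."""
    from .tfm import BeadImagePair

    extent = config.field_size
    n_px = int(round(extent / config.pixel_size))
    n_beads = rng.poisson(config.bead_density * extent * extent)
    bx = rng.uniform(0, extent, n_beads)
    by = rng.uniform(0, extent, n_beads)
    # sample displacement at bead positions (grid is centred on 0)
    gx0 = disp.grid_x[0, 0]
    gy0 = disp.grid_y[0, 0]
    d = disp.spacing
    ix = np.clip((bx - (gx0 + extent / 2) - 0) / d, 0, disp.u.shape[1] - 1)
    iy = np.clip((by - (gy0 + extent / 2) - 0) / d, 0, disp.u.shape[0] - 1)
    from scipy.ndimage import map_coordinates

    ub = map_coordinates(disp.u, [iy, ix], order=1)
    vb = map_coordinates(disp.v, [iy, ix], order=1)

    def render(xs, ys):
        img = np.zeros((n_px, n_px))
        px = xs / config.pixel_size
        py = ys / config.pixel_size
        sigma = 1.0  # px, ~1 µm bead PSF
        for x0, y0 in zip(px, py):
            x0i, y0i = int(round(x0)), int(round(y0))
            lo_x, hi_x = max(x0i - 4, 0), min(x0i + 5, n_px)
            lo_y, hi_y = max(y0i - 4, 0), min(y0i + 5, n_px)
            if lo_x >= hi_x or lo_y >= hi_y:
                continue
            yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
            img[lo_y:hi_y, lo_x:hi_x] += np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
            )
        return img

    relaxed = render(bx, by)
    reference = render(bx + ub, by + vb)  # stressed: beads displaced by u
    return BeadImagePair(reference=reference, relaxed=relaxed, pixel_size=config.pixel_size)


def generate_stress_gradient_truth(b: float, lattice: HexLattice) -> dict:
    """Per-cell stress values σ_i = b·ρ_i with their generating record."""
    if b < 0:
        raise ValueError("b must be >= 0")
    return {
        "sigma": float(b) * lattice.radius_norm,
        "truth": {"b": float(b), "form": "linear_in_radius_norm"},
    }
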