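"""Traction force microscopy: bead displacements to traction stresses.

The pipeline mirrors standard TFM practice for cells on elastic gels:

1. **DIC** — windowed normalised cross-correlation between the stressed
   (cells attached) and relaxed (after lysis) bead images yields a regular
   grid of in-plane displacements, with subpixel peak localisation,
   quality masking and inpainting.
2. **FTTC** — the displacement field is inverted to traction through the
   Boussinesq elastic half-space surface Green's function, evaluated
   spectrally with zeroth-order Tikhonov regularisation.
3. **Reduction** — per-island traction maps are reduced to radial
   statistics over the dimensionless radius R = distance / effective island
   radius (best-fit ellipse).

Sign/units conventions: displacements in µm (``u`` = stressed − relaxed
bead position), tractions in Pa exerted *by the cells on the gel*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .profiles import RadialProfile, bin_mean_profile

__all__ = [
    "BeadImagePair",
    "DisplacementField",
    "TractionField",
    "IslandFit",
    "dic_displacement",
    "forward_displacement",
    "fttc",
    "fit_island",
    "radial_traction_profile",
    "central_mean_stress",
    "select_lambda_lcurve",
]

logger = logging.getLogger(__name__)


@dataclass
class BeadImagePair:
    """Fluorescent-bead images before (stressed) and after (relaxed) lysis."""

    reference: np.ndarray
    relaxed: np.ndarray
    pixel_size: float  # µm/px

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.relaxed = np.asarray(self.relaxed, dtype=float)
        if self.reference.shape != self.relaxed.shape:
            raise ValueError("reference and relaxed images must have equal dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class DisplacementField:
    """In-plane displacements on a regular grid (all lengths in µm)."""

    grid_x: np.ndarray  # (ny, nx)
    grid_y: np.ndarray
    u: np.ndarray  # x-displacement
    v: np.ndarray  # y-displacement
    correlation_quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("grid_x", "grid_y", "u", "v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.grid_x.shape == self.grid_y.shape == self.u.shape == self.v.shape):
            raise ValueError("grid and displacement arrays must share one shape")

    @property
    def spacing(self) -> float:
        dx = np.diff(self.grid_x[0]) if self.grid_x.ndim == 2 else np.diff(self.grid_x)
        dy = np.diff(self.grid_y[:, 0]) if self.grid_y.ndim == 2 else np.diff(self.grid_y)
        if dx.size and (np.ptp(dx) > 1e-6 * abs(dx[0]) or (dy.size and np.ptp(dy) > 1e-6 * abs(dy[0]))):
            raise ValueError("grid is not regular; regrid before inversion")
        return float(dx[0])


@dataclass
class TractionField:
    """Traction stresses on the displacement grid, with inversion metadata."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    t_x: np.ndarray  # Pa
    t_y: np.ndarray  # Pa
    substrate_E: float  # Pa
    substrate_nu: float
    regularization: float  # Tikhonov λ (same units as the kernel, ≥ 0)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)

    @property
    def spacing(self) -> float:
        return float(self.grid_x[0, 1] - self.grid_x[0, 0])


@dataclass
class IslandFit:
    """Best-fit ellipse of an island border."""

    centroid: tuple[float, float]  # µm
    semi_axes: tuple[float, float]  # µm
    orientation: float  # rad

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be > 0")

    @property
    def effective_radius(self) -> float:
        """Geometric mean of the semi-axes."""
        return float(np.sqrt(self.semi_axes[0] * self.semi_axes[1]))


# ---------------------------------------------------------------------------
# digital image correlation


def _subpixel_parabolic(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Parabolic 3-point refinement of a correlation peak, per axis."""
    i, j = peak
    out = [float(i), float(j)]
    for ax, idx in enumerate((i, j)):
        if idx <= 0 or idx >= corr.shape[ax] - 1:
            continue
        if ax == 0:
            c0, c1, c2 = corr[idx - 1, j], corr[idx, j], corr[idx + 1, j]
        else:
            c0, c1, c2 = corr[i, idx - 1], corr[i, idx], corr[i, idx + 1]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-12:
            out[ax] = idx + 0.5 * (c0 - c2) / denom
    return out[0], out[1]


def dic_displacement(
    pair: BeadImagePair,
    window_px: int = 32,
    overlap_frac: float = 0.5,
    search_px: int | None = None,
    peak_ratio_min: float = 1.2,
    median_filter: bool = True,
) -> DisplacementField:
    """Displacement field between the relaxed and stressed bead images.

    Each interrogation window of the *relaxed* image is located in the
    *stressed* (reference) image by normalised cross-correlation with
    parabolic subpixel refinement.  Nodes whose correlation peak is less
    than ``peak_ratio_min`` times the second-highest peak (or whose window
    has no texture) are masked and inpainted from their neighbours.
    """
    from skimage.feature import match_template

    if window_px < 16:
        raise ValueError("window_px must be >= 16")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    if search_px is None:
        search_px = window_px // 2
    ref, rel = pair.reference, pair.relaxed
    step = max(int(round(window_px * (1 - overlap_frac))), 1)
    ny_img, nx_img = rel.shape

    centers_y = np.arange(window_px // 2, ny_img - window_px // 2 + 1, step)
    centers_x = np.arange(window_px // 2, nx_img - window_px // 2 + 1, step)
    u = np.zeros((centers_y.size, centers_x.size))
    v = np.zeros_like(u)
    quality = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)

    half = window_px // 2
    for iy, cy in enumerate(centers_y):
        for ix, cx in enumerate(centers_x):
            tmpl = rel[cy - half : cy + half, cx - half : cx + half]
            if tmpl.std() == 0:
                warnings.warn(f"featureless window at node ({iy}, {ix}); masked")
                continue
            y0, y1 = max(cy - half - search_px, 0), min(cy + half + search_px, ny_img)
            x0, x1 = max(cx - half - search_px, 0), min(cx + half + search_px, nx_img)
            sub = ref[y0:y1, x0:x1]
            if sub.shape[0] < window_px or sub.shape[1] < window_px or sub.std() == 0:
                continue
            corr = match_template(sub, tmpl)
            k = np.unravel_index(np.argmax(corr), corr.shape)
            peak_val = corr[k]
            # peak-ratio quality: best vs second-best after masking a 3-px
            # neighbourhood of the best
            masked = corr.copy()
            ky0, ky1 = max(k[0] - 3, 0), min(k[0] + 4, corr.shape[0])
            kx0, kx1 = max(k[1] - 3, 0), min(k[1] + 4, corr.shape[1])
            masked[ky0:ky1, kx0:kx1] = -np.inf
            second = masked.max() if np.isfinite(masked).any() else -1.0
            ratio = (peak_val + 1.0) / (second + 1.0)  # shift to positive scale
            py, px = _subpixel_parabolic(corr, k)
            dy = (y0 + py) - (cy - half)
            dx = (x0 + px) - (cx - half)
            u[iy, ix] = dx * pair.pixel_size
            v[iy, ix] = dy * pair.pixel_size
            quality[iy, ix] = float(np.clip(peak_val, 0.0, 1.0))
            valid[iy, ix] = ratio >= peak_ratio_min or second == -1.0

    if median_filter and valid.sum() > 8:
        for comp in (u, v):
            med = ndimage.median_filter(comp, size=3)
            resid = np.abs(comp - med)
            scale = np.median(resid[valid]) + 1e-12
            outlier = resid > 10 * scale
            valid &= ~outlier

    gx = centers_x[None, :].repeat(centers_y.size, axis=0) * pair.pixel_size
    gy = centers_y[:, None].repeat(centers_x.size, axis=1) * pair.pixel_size
    if not valid.all():
        if valid.sum() < 3:
            raise RuntimeError("too few valid correlation nodes to inpaint")
        pts = np.column_stack([gx[valid], gy[valid]])
        bad = ~valid
        for comp in (u, v):
            filled = griddata(pts, comp[valid], (gx[bad], gy[bad]), method="linear")
            nearest = griddata(pts, comp[valid], (gx[bad], gy[bad]), method="nearest")
            comp[bad] = np.where(np.isnan(filled), nearest, filled)
    return DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v, correlation_quality=quality)


# ---------------------------------------------------------------------------
# spectral half-space elasticity


def _boussinesq_kernel(kx: np.ndarray, ky: np.ndarray, E: float, nu: float):
    """Per-wavevector 2x2 surface Green's tensor of the elastic half-space.

    û_i(k) = G_ij(k) t̂_j(k), with G in µm/Pa when k is in rad/µm:

        G = 2(1+ν) / (E k³) · [[(1−ν)k² + ν k_y²,  −ν k_x k_y],
                               [−ν k_x k_y,        (1−ν)k² + ν k_x²]]

    The k = 0 entry is set to zero: a uniform traction on an infinite
    half-space has no finite displacement, and rigid drift carries no
    traction.
    """
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2 * k)
        Gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        Gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        Gxy = pref * (-nu * kx * ky)
    for arr in (Gxx, Gyy, Gxy):
        arr[k2 == 0] = 0.0
    return Gxx, Gyy, Gxy


def _padded_shape(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(2 * n)


def forward_displacement(
    traction: TractionField,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    pad: bool = True,
) -> DisplacementField:
    """Surface displacement generated by a traction field (Boussinesq).

    Evaluated spectrally with zero padding to twice the field size so the
    periodic images of the FFT do not wrap around.  The zero-frequency
    component is dropped, so only zero-mean structure displaces; output is
    on the traction grid (``grid`` is accepted for interface symmetry and
    must match).
    """
    if grid is not None:
        if not (np.allclose(grid[0], traction.grid_x) and np.allclose(grid[1], traction.grid_y)):
            raise ValueError("output grid must equal the traction grid")
    d = traction.spacing
    ny, nx = traction.t_x.shape
    py, px = (_padded_shape(ny), _padded_shape(nx)) if pad else (ny, nx)
    tx = np.zeros((py, px))
    ty = np.zeros((py, px))
    tx[:ny, :nx] = traction.t_x
    ty[:ny, :nx] = traction.t_y
    kx = 2 * np.pi * np.fft.fftfreq(px, d=d)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(py, d=d)[:, None]
    Gxx, Gyy, Gxy = _boussinesq_kernel(kx, ky, traction.substrate_E, traction.substrate_nu)
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    u = np.real(np.fft.ifft2(Gxx * ftx + Gxy * fty))[:ny, :nx]
    v = np.real(np.fft.ifft2(Gxy * ftx + Gyy * fty))[:ny, :nx]
    return DisplacementField(
        grid_x=traction.grid_x, grid_y=traction.grid_y, u=u, v=v
    )


def fttc(
    displacement: DisplacementField,
    substrate_E: float,
    substrate_nu: float,
    lambda_reg: float = 0.0,
    window: bool = False,
    pad: bool = True,
    subtract_drift: bool = True,
) -> TractionField:
    """Fourier-transform traction cytometry with Tikhonov regularisation.

    Solves, per wavevector, ``t̂ = (Gᵀ G + λ² I)⁻¹ Gᵀ û`` where G is the
    Boussinesq surface kernel; λ = 0 is the unregularised inverse.  The
    field is zero-padded (and optionally Hann-windowed) to suppress
    wrap-around; the mean displacement (rigid drift, the kernel's excluded
    zero-frequency component) is removed first.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    d = displacement.spacing  # raises on irregular grids
    u, v = displacement.u, displacement.v
    if subtract_drift:
        u = u - u.mean()
        v = v - v.mean()
    ny, nx = u.shape
    if window:
        wy = np.hanning(ny)[:, None]
        wx = np.hanning(nx)[None, :]
        u = u * wy * wx
        v = v * wy * wx
    py, px = (_padded_shape(ny), _padded_shape(nx)) if pad else (ny, nx)
    up = np.zeros((py, px))
    vp = np.zeros((py, px))
    up[:ny, :nx] = u
    vp[:ny, :nx] = v
    kx = 2 * np.pi * np.fft.fftfreq(px, d=d)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(py, d=d)[:, None]
    Gxx, Gyy, Gxy = _boussinesq_kernel(kx, ky, substrate_E, substrate_nu)
    fu = np.fft.fft2(up)
    fv = np.fft.fft2(vp)
    # (GᵀG + λ²I)⁻¹ Gᵀ for the symmetric 2x2 kernel, closed form
    a = Gxx * Gxx + Gxy * Gxy + lambda_reg**2
    b = Gxy * (Gxx + Gyy)
    c = Gxy * Gxy + Gyy * Gyy + lambda_reg**2
    det = a * c - b * b
    rhs_x = Gxx * fu + Gxy * fv
    rhs_y = Gxy * fu + Gyy * fv
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (c * rhs_x - b * rhs_y) / det
        fty = (a * rhs_y - b * rhs_x) / det
    zero = (kx**2 + ky**2) == 0
    ftx[zero] = 0.0
    fty[zero] = 0.0
    tx = np.real(np.fft.ifft2(ftx))[:ny, :nx]
    ty = np.real(np.fft.ifft2(fty))[:ny, :nx]
    return TractionField(
        grid_x=displacement.grid_x,
        grid_y=displacement.grid_y,
        t_x=tx,
        t_y=ty,
        substrate_E=substrate_E,
        substrate_nu=substrate_nu,
        regularization=lambda_reg,
    )


def select_lambda_lcurve(
    displacement: DisplacementField,
    substrate_E: float,
    substrate_nu: float,
    lambdas: np.ndarray | None = None,
) -> float:
    """L-curve heuristic for the Tikhonov parameter.

    Scans λ over a logarithmic grid and returns the corner of the
    (log residual norm, log solution norm) curve, located as the point of
    maximum distance from the chord joining the curve's endpoints — a
    robust variant of the maximum-curvature criterion.
    """
    if lambdas is None:
        # scale λ to the kernel magnitude at the grid Nyquist scale
        d = displacement.spacing
        g_scale = 2 * (1 + substrate_nu) / (substrate_E * (np.pi / d))
        lambdas = g_scale * np.logspace(-3, 2, 25)
    res, sol = [], []
    for lam in lambdas:
        t = fttc(displacement, substrate_E, substrate_nu, lambda_reg=lam)
        u_hat = forward_displacement(t)
        res.append(
            np.sqrt(np.mean((u_hat.u - displacement.u) ** 2 + (u_hat.v - displacement.v) ** 2))
        )
        sol.append(np.sqrt(np.mean(t.t_x**2 + t.t_y**2)))
    x = np.log(np.maximum(res, 1e-300))
    y = np.log(np.maximum(sol, 1e-300))
    # normalise both axes, then find the point farthest from the chord
    x = (x - x.min()) / max(x.max() - x.min(), 1e-300)
    y = (y - y.min()) / max(y.max() - y.min(), 1e-300)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, y]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return float(lambdas[int(np.argmax(dist))])


# ---------------------------------------------------------------------------
# island geometry and radial reduction


def fit_island(border_points: np.ndarray) -> IslandFit:
    """Least-squares ellipse through island border points (µm).

    Accepts an ``(n, 2)`` array of border coordinates (n ≥ 5) or a boolean
    mask image interpreted at unit pixel size.
    """
    pts = np.asarray(border_points)
    if pts.dtype == bool:
        from skimage import measure

        contours = measure.find_contours(pts.astype(float), 0.5)
        if not contours:
            raise ValueError("empty mask")
        c = max(contours, key=len)
        pts = c[:, ::-1]  # (row, col) -> (x, y)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("border points must be (n, 2)")
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 border points")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] == 0 or sv[1] < 1e-8 * sv[0]:
        raise ValueError("degenerate border points; points are collinear")
    from skimage.measure import EllipseModel

    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError(f"degenerate border points; ellipse fit failed ({model})")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise ValueError("degenerate border points; ellipse fit failed")
    return IslandFit(centroid=(float(xc), float(yc)), semi_axes=(float(a), float(b)),
                     orientation=float(theta))


def _dimensionless_radius(field_x, field_y, island: IslandFit) -> np.ndarray:
    dx = field_x - island.centroid[0]
    dy = field_y - island.centroid[1]
    return np.hypot(dx, dy) / island.effective_radius


def radial_traction_profile(
    traction: TractionField,
    island: IslandFit,
    n_bins: int = 30,
    r_max: float = 1.2,
) -> RadialProfile:
    """Mean traction magnitude per dimensionless-radius bin, with 95% CI."""
    R = _dimensionless_radius(traction.grid_x, traction.grid_y, island)
    if R.min() > 1.0:
        raise ValueError("island lies outside the traction grid")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    return bin_mean_profile(
        R.ravel(), traction.magnitude.ravel(), edges,
        statistic="mean_traction_pa", with_ci=True,
    )


def central_mean_stress(
    traction: TractionField, island: IslandFit, r_cut: float = 0.75
) -> float:
    """Mean traction magnitude over the island centre (R < ``r_cut``), Pa."""
    if not (0 < r_cut <= 1):
        raise ValueError("r_cut must be in (0, 1]")
    R = _dimensionless_radius(traction.grid_x, traction.grid_y, island)
    inside = R < r_cut
    if not inside.any():
        raise ValueError("no grid nodes inside the central cut")
    return float(traction.magnitude[inside].mean())
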