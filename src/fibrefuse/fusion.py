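"""MRI-microscopy fusion: plane projection, FOD comparison, hybrid 3D axes.

2D microscopy (polarimetry or stained histology) measures fibre orientations
within the section plane at micrometre resolution; diffusion MRI measures 3D
orientations at millimetre resolution. This module (i) projects 3D axes and
orientation samples onto a section plane for like-for-like 2D comparison,
(ii) builds and compares 2-degree-binned 2D FODs and their dispersion, and
(iii) reconstructs *hybrid* 3D fibre orientations — microscopy in-plane angle
combined with the through-plane (inclination) angle of the most similar
ball-and-stick orientation sample — which are binned on a 256-point sphere
histogram and fitted with order-8 real even spherical harmonics for export
to standard tractography formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .histology import fit_axial_concentration, odi_from_kappa
from .sphere import symmetric_sphere_grid

log = logging.getLogger(__name__)

__all__ = [
    "PlaneFrame",
    "FOD2D",
    "FOD3D",
    "HybridOrientationMap",
    "project_to_plane",
    "build_fod2d",
    "odi_of_fod2d",
    "linreg_ftest",
    "match_hybrid_orientations",
    "build_fod3d",
    "real_sh_basis",
    "fit_sh",
    "export_sh_image",
]


@dataclass
class PlaneFrame:
    """Geometry of a microscopy section within the 3D volume.

    Pixel (row r, column c) of the section maps to the world-space (mm) point

        origin + (c + 1/2) * ps * e1 + (r + 1/2) * ps * e2

    with ps the pixel size in mm, so in-plane angles measured from the image
    +x (column) axis towards +y (rows) correspond to angles from e1 towards
    e2. {e1, e2, n} is right-handed orthonormal with n = e1 x e2.
    """

    origin_mm: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    pixel_size_um: float
    section_thickness_um: float = 50.0

    def __post_init__(self):
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.e1 = np.asarray(self.e1, dtype=float)
        self.e2 = np.asarray(self.e2, dtype=float)
        for v in (self.e1, self.e2):
            if abs(np.linalg.norm(v) - 1) > 1e-8:
                raise ValueError("plane basis vectors must be unit norm")
        if abs(self.e1 @ self.e2) > 1e-8:
            raise ValueError("plane basis vectors must be orthogonal")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.e1, self.e2)

    def pixel_to_mm(self, rows, cols) -> np.ndarray:
        ps = self.pixel_size_um / 1000.0
        r = np.asarray(rows, dtype=float)[..., None]
        c = np.asarray(cols, dtype=float)[..., None]
        return self.origin_mm + (c + 0.5) * ps * self.e1 + (r + 0.5) * ps * self.e2

    def pixel_to_voxel(self, rows, cols, voxel_size_mm) -> np.ndarray:
        """Integer voxel indices of pixels for a grid with origin at 0 mm."""
        vs = np.asarray(voxel_size_mm, dtype=float)
        return np.floor(self.pixel_to_mm(rows, cols) / vs).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin_mm": self.origin_mm.tolist(),
                "e1": self.e1.tolist(),
                "e2": self.e2.tolist(),
                "normal": self.normal.tolist(),
                "pixel_size_um": self.pixel_size_um,
                "section_thickness_um": self.section_thickness_um,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PlaneFrame":
        d = json.loads(text)
        return cls(
            np.array(d["origin_mm"]), np.array(d["e1"]), np.array(d["e2"]),
            d["pixel_size_um"], d.get("section_thickness_um", 50.0),
        )


def project_to_plane(axis: np.ndarray, frame: PlaneFrame, eps: float = 1e-8):
    """Project 3D axes onto the section plane.

    Returns ``(angle_deg, magnitude)``: the axial in-plane angle in
    [0, 180) measured from e1 towards e2, and the length of the in-plane
    component. Axes within ``eps`` of the plane normal have undefined angle
    (returned as NaN).
    """
    a = np.asarray(axis, dtype=float)
    x = a @ frame.e1
    y = a @ frame.e2
    mag = np.hypot(x, y)
    with np.errstate(invalid="ignore"):
        ang = np.mod(np.degrees(np.arctan2(y, x)), 180.0)
    ang = np.where(mag < eps, np.nan, ang)
    if np.ndim(a) == 1:
        return float(ang), float(mag)
    return ang, mag


@dataclass
class FOD2D:
    """Axial 2D fibre orientation distribution on 2-degree bins."""

    weights: np.ndarray
    bin_deg: float = 2.0
    normalised: bool = True

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (np.arange(len(self.weights)) + 0.5) * self.bin_deg


def build_fod2d(angles_deg, weights=None, bin_deg: float = 2.0) -> FOD2D:
    """Weighted axial histogram over [0, 180) with ``bin_deg`` bins."""
    ang = np.mod(np.asarray(angles_deg, dtype=float).ravel(), 180.0)
    if ang.size == 0:
        raise ValueError("empty angle set")
    n_bins = int(round(180.0 / bin_deg))
    w = None if weights is None else np.asarray(weights, float).ravel()
    hist, _ = np.histogram(ang, bins=n_bins, range=(0.0, 180.0), weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram has zero total weight")
    return FOD2D(hist / total, bin_deg=bin_deg)


def odi_of_fod2d(fod: FOD2D) -> float:
    """Orientation dispersion index of a 2D FOD (via the axial von Mises fit)."""
    if not np.isfinite(fod.weights).all() or fod.weights.sum() <= 0:
        raise ValueError("invalid FOD")
    kappa = fit_axial_concentration(fod.bin_centers_deg, fod.weights)
    return odi_from_kappa(kappa)


@dataclass
class LinRegResult:
    slope: float
    intercept: float
    r: float
    p: float
    f_stat: float
    n: int
    band_x: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def linreg_ftest(x, y) -> LinRegResult:
    """Ordinary least squares with an F-test against the constant-only model.

    F = (n - 2) * R^2 / (1 - R^2) on (1, n - 2) degrees of freedom — for
    simple regression this is the standard model-comparison F-test. 95%
    confidence bands for the mean response are evaluated on a grid spanning x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired finite values")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise ValueError("zero variance in x")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    r = float(np.sign(slope) * np.sqrt(max(r2, 0.0)))
    if r2 >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    s2 = np.sum(resid**2) / (n - 2)
    tcrit = stats.t.ppf(0.975, n - 2)
    gx = np.linspace(x.min(), x.max(), 100)
    half = tcrit * np.sqrt(s2 * (1.0 / n + (gx - x.mean()) ** 2 / sxx))
    yhat = intercept + slope * gx
    return LinRegResult(
        float(slope), float(intercept), r, p, float(f_stat), n,
        gx, yhat - half, yhat + half,
    )


@dataclass
class HybridOrientationMap:
    """Per-microscopy-pixel hybrid 3D fibre orientations."""

    axes: np.ndarray          # (H, W, 3) unit axes
    source_population: np.ndarray  # (H, W) int, -1 where invalid
    match_diff_deg: np.ndarray     # (H, W) in-plane axial matching difference
    valid: np.ndarray              # (H, W) bool
    frame: PlaneFrame = field(repr=False, default=None)  # type: ignore[assignment]


def _axial_diff_deg(a, b):
    return np.abs(np.mod(np.asarray(a) - np.asarray(b) + 90.0, 180.0) - 90.0)


def match_hybrid_orientations(
    pli_maps,
    bas_fit,
    frame: PlaneFrame,
    f_threshold: float = 0.05,
) -> HybridOrientationMap:
    """Combine microscopy in-plane angles with dMRI through-plane angles.

    For every valid microscopy pixel, the ball-and-stick orientation samples
    of the containing dMRI voxel (populations with signal fraction >=
    ``f_threshold`` only) are projected onto the section plane; the sample
    whose in-plane angle is axially most similar to the microscopy angle
    lends its through-plane (inclination) angle. The hybrid axis is

        v = cos(a) cos(phi) e1 + cos(a) sin(phi) e2 + sin(a) n

    with phi the microscopy in-plane angle and a the matched sample's
    inclination. Ties are broken by higher population fraction, then lower
    sample index. Pixels whose voxel has no population above threshold are
    flagged invalid.
    """
    h, w = pli_maps.angle.shape
    axes = np.zeros((h, w, 3))
    src = np.full((h, w), -1, dtype=int)
    diff = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    vox = frame.pixel_to_voxel(rr.ravel(), cc.ravel(), bas_fit.voxel_size_mm)
    vox = vox.reshape(h, w, 3)
    e1, e2, nrm = frame.e1, frame.e2, frame.normal

    # group pixels by voxel so samples are projected once per voxel
    flat_ok = pli_maps.valid.ravel()
    keys = [tuple(v) for v in vox.reshape(-1, 3)]
    from collections import defaultdict

    groups = defaultdict(list)
    for idx, (k, ok) in enumerate(zip(keys, flat_ok)):
        if ok:
            groups[k].append(idx)

    for key, pix_idx in groups.items():
        vdata = bas_fit.voxel(key)
        if vdata is None:
            continue
        fracs, samples = vdata  # (P,), (P, S, 3)
        keep = fracs >= f_threshold
        if not keep.any():
            continue
        fracs, samples = fracs[keep], samples[keep]
        pops = np.nonzero(keep)[0]
        p_, s_, _ = samples.shape
        flat = samples.reshape(-1, 3)
        sx, sy, sn = flat @ e1, flat @ e2, flat @ nrm
        inplane = np.hypot(sx, sy)
        samp_ang = np.mod(np.degrees(np.arctan2(sy, sx)), 180.0)
        # inclination magnitude of each sample; sign resolved per pixel below
        incl = np.arctan2(np.abs(sn), inplane)  # radians, [0, pi/2]
        frac_of = np.repeat(fracs, s_)
        samp_of = np.tile(np.arange(s_), p_)
        pop_of = np.repeat(pops, s_)

        ang_pix = pli_maps.angle.ravel()[pix_idx]
        d = _axial_diff_deg(samp_ang[None, :], np.asarray(ang_pix)[:, None])
        d = np.where(inplane[None, :] < 1e-8, np.inf, d)
        for i, row in enumerate(pix_idx):
            if not np.isfinite(d[i]).any():
                continue
            # tie-break: smallest diff, then largest fraction, then sample idx
            j = int(np.lexsort((samp_of, -frac_of, np.round(d[i], 9)))[0])
            r_i, c_i = divmod(row, w)
            phi = np.radians(pli_maps.angle[r_i, c_i])
            a = incl[j]
            v = (
                np.cos(a) * np.cos(phi) * e1
                + np.cos(a) * np.sin(phi) * e2
                + np.sin(a) * nrm
            )
            axes[r_i, c_i] = v / np.linalg.norm(v)
            src[r_i, c_i] = int(pop_of[j])
            diff[r_i, c_i] = _axial_diff_deg(samp_ang[j], pli_maps.angle[r_i, c_i])
            valid[r_i, c_i] = True
    return HybridOrientationMap(axes, src, diff, valid, frame)


@dataclass
class FOD3D:
    """Sphere-histogram FODs on an antipodally paired point grid.

    ``weights`` maps voxel index tuples to normalised weight vectors over
    ``points`` (length 256 by default; point k and k + n/2 are negatives and
    share each axis's weight).
    """

    points: np.ndarray
    weights: dict
    grid_shape: tuple
    voxel_size_mm: np.ndarray


def build_fod3d(
    hybrid_map: HybridOrientationMap,
    voxel_size_mm,
    grid_shape=None,
    n_points: int = 256,
) -> FOD3D:
    """Bin hybrid axes into per-voxel sphere histograms.

    The output voxel grid may be finer or coarser than the dMRI grid. Each
    valid axis contributes half a count to its nearest grid point under the
    axial metric (max |v . p|) and half to that point's antipode, so the
    histogram is exactly symmetric under v -> -v. Weights are normalised
    per voxel.
    """
    pts = symmetric_sphere_grid(n_points)
    half = n_points // 2
    vs = np.asarray(voxel_size_mm, dtype=float) * np.ones(3)
    rr, cc = np.nonzero(hybrid_map.valid)
    axes = hybrid_map.axes[rr, cc]
    vox = hybrid_map.frame.pixel_to_voxel(rr, cc, vs)
    if grid_shape is None:
        grid_shape = tuple(vox.max(axis=0) + 1) if len(vox) else (0, 0, 0)
    weights: dict = {}
    if len(axes):
        nearest = np.argmax(np.abs(axes @ pts.T), axis=1)
        partner = np.where(nearest >= half, nearest - half, nearest + half)
        for v, q, qb in zip(map(tuple, vox), nearest, partner):
            wv = weights.setdefault(v, np.zeros(n_points))
            wv[q] += 0.5
            wv[qb] += 0.5
    for v in weights:
        weights[v] /= weights[v].sum()
    return FOD3D(pts, weights, tuple(grid_shape), vs)


def real_sh_basis(lmax: int, points: np.ndarray) -> np.ndarray:
    """Real even-order spherical-harmonic design matrix at unit ``points``.

    Ordering: l = 0, 2, ..., lmax, and within each l, m = -l ... l — the
    real-basis ordering used by common tractography software. For m > 0 the
    function is sqrt(2) * (-1)^m * Re(Y_l^m); for m < 0, sqrt(2) * (-1)^m *
    Im(Y_l^|m|); m = 0 is the real Y_l^0.
    """
    p = np.asarray(points, dtype=float)
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(p[:, 1], p[:, 0])              # azimuth
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = special.sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.stack(cols, axis=1)


def n_sh_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def fit_sh(fod: FOD3D, lmax: int = 8) -> dict:
    """Least-squares real even-order SH coefficients of each voxel's FOD.

    Returns a dict mapping voxel index tuples to coefficient vectors of
    length (lmax + 1)(lmax + 2)/2 (45 for lmax = 8).
    """
    basis = real_sh_basis(lmax, fod.points)
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("rank-deficient SH design matrix")
    pinv = np.linalg.pinv(basis)
    return {v: pinv @ w for v, w in fod.weights.items()}


def export_sh_image(coeffs: dict, grid_shape, voxel_size_mm, out_path, lmax: int = 8):
    """Write SH coefficients as a 4D NIfTI plus a JSON basis sidecar."""
    import nibabel as nib

    nc = n_sh_coeffs(lmax)
    vol = np.zeros(tuple(grid_shape) + (nc,), dtype=np.float32)
    for v, c in coeffs.items():
        vol[v] = c
    affine = np.diag(list(np.asarray(voxel_size_mm, float) * np.ones(3)) + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms(tuple(np.asarray(voxel_size_mm, float) * np.ones(3)) + (1.0,))
    nib.save(img, str(out_path))
    sidecar = {
        "basis": "real even-order spherical harmonics",
        "lmax": lmax,
        "n_coefficients": nc,
        "ordering": "l = 0,2,...,lmax; within each l, m = -l..l",
        "m_convention": "m<0: sqrt2*(-1)^m*Im(Y_l^|m|); m=0: Y_l^0; m>0: sqrt2*(-1)^m*Re(Y_l^m)",
    }
    side_path = str(out_path) + ".json"
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out_path
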