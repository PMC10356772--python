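"""Diffusion MRI and relaxometry model fitting.

Preprocessing (signal-drift regression, S0 normalisation), the diffusion
tensor, the Ball and Stick model (isotropic ball + up to three zero-radius
stick compartments, with bootstrap orientation samples), the Ball and
Rackets model (a single Bingham-dispersed stick), joint analysis of linear
and spherical b-tensor encoding via the gamma-distribution signal
representation (microscopic FA), and the three-parameter inversion-recovery
T1 model S(TI) = a + b exp(-TI / T1).

Units: b in ms/um^2, diffusivities in um^2/ms, TI and T1 in ms.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .gradients import GradientScheme
from .sphere import symmetric_sphere_grid

log = logging.getLogger(__name__)

__all__ = [
    "DWIVolume",
    "TensorMaps",
    "BASFit",
    "BARFit",
    "DivideMaps",
    "T1Maps",
    "correct_drift",
    "normalise_s0",
    "fit_dti",
    "fit_ball_and_stick",
    "orientation_precision",
    "fit_ball_and_rackets",
    "fit_divide",
    "fit_t1",
]


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted dataset with its acquisition scheme."""

    data: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray | None = None
    s0_times: np.ndarray | None = None
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, volume)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError("4th dimension must match scheme length")
        if np.any(self.data < 0):
            raise ValueError("signals must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float) * np.ones(3)

    @property
    def grid_shape(self):
        return self.data.shape[:3]


def correct_drift(dwi: DWIVolume) -> DWIVolume:
    """Regress a linear-in-time signal drift out of the data.

    A line c0 + c1 t is least-squares fitted to the mean b~0 intensities at
    the recorded ``s0_times``; every volume is then divided by the relative
    trend (1 + c1 t / c0) at its (interpolated) acquisition time, so
    corrected b~0 means are constant in time.
    """
    b0_idx = np.nonzero(dwi.scheme.is_b0)[0]
    if dwi.s0_times is None or len(b0_idx) < 2:
        raise ValueError("need >= 2 b~0 volumes with acquisition times")
    t0 = np.asarray(dwi.s0_times, dtype=float)
    if len(t0) != len(b0_idx):
        raise ValueError("s0_times length must match the number of b~0 volumes")
    means = dwi.data[dwi.mask][:, b0_idx].mean(axis=0)
    c1, c0 = np.polyfit(t0, means, 1)
    if c0 <= 0:
        raise ValueError("non-positive fitted baseline intensity")
    t_all = np.interp(np.arange(len(dwi.scheme)), b0_idx, t0)
    trend = 1.0 + c1 * t_all / c0
    return DWIVolume(dwi.data / trend, dwi.scheme, dwi.mask, dwi.s0_times,
                     dwi.voxel_size_mm)


def normalise_s0(dwi: DWIVolume, reference: np.ndarray | None = None) -> DWIVolume:
    """Divide voxelwise by a reference b~0 volume (default: mean b~0).

    Voxels with zero reference are removed from the mask; the count of such
    voxels is logged.
    """
    if reference is None:
        reference = dwi.data[..., dwi.scheme.is_b0].mean(axis=-1)
    reference = np.asarray(reference, dtype=float)
    zero = reference <= 0
    n_zero = int(np.sum(zero & dwi.mask))
    if n_zero:
        log.info("normalise_s0: masking %d zero-reference voxels", n_zero)
    safe = np.where(zero, 1.0, reference)
    out = DWIVolume(dwi.data / safe[..., None], dwi.scheme,
                    dwi.mask & ~zero, dwi.s0_times, dwi.voxel_size_mm)
    out.n_zero_reference = n_zero  # accounting for callers
    return out


# ---------------------------------------------------------------- DTI ----

@dataclass
class TensorMaps:
    fa: np.ndarray
    md: np.ndarray
    v1: np.ndarray
    tensor: np.ndarray
    s0: np.ndarray
    mask: np.ndarray


def _dti_design(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.directions
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def fit_dti(dwi: DWIVolume) -> TensorMaps:
    """Log-linear least-squares diffusion tensor fit.

    Requires at least 6 unique directions plus b~0. Non-positive signals are
    excluded from the log fit per voxel. Returns FA in [0, 1], MD in
    um^2/ms and the primary eigenvector V1.
    """
    dw = ~dwi.scheme.is_b0
    if len(np.unique(np.round(dwi.scheme.directions[dw], 6), axis=0)) < 6:
        raise ValueError("need at least 6 unique diffusion directions")
    design = _dti_design(dwi.scheme)
    shape = dwi.grid_shape
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    v1 = np.full(shape + (3,), np.nan)
    tensor = np.full(shape + (3, 3), np.nan)
    idx = np.argwhere(dwi.mask)
    full_pinv = np.linalg.pinv(design)
    for vx in idx:
        y = dwi.data[tuple(vx)]
        pos = y > 0
        if pos.sum() < 7:
            continue
        if pos.all():
            coef = full_pinv @ np.log(y)
        else:
            coef, *_ = np.linalg.lstsq(design[pos], np.log(y[pos]), rcond=None)
        dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
        dmat = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
        evals, evecs = np.linalg.eigh(dmat)
        lam = evals[::-1]
        mean_d = lam.mean()
        denom = np.sum(lam**2)
        f = 0.0 if denom == 0 else np.sqrt(1.5 * np.sum((lam - mean_d) ** 2) / denom)
        t = tuple(vx)
        fa[t] = min(float(f), 1.0)
        md[t] = mean_d
        s0[t] = np.exp(coef[0])
        v1[t] = evecs[:, -1]
        tensor[t] = dmat
    return TensorMaps(fa, md, v1, tensor, s0, dwi.mask)


# ------------------------------------------------------- Ball and Stick ----

def _sph_to_vec(theta, phi):
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _vec_to_sph(v):
    v = v / np.linalg.norm(v)
    return np.arccos(np.clip(v[2], -1, 1)), np.arctan2(v[1], v[0])


def _stick_fractions(ws):
    """Stick-breaking map from k values in [0, 1] to fractions summing <= 1."""
    fr = []
    rem = 1.0
    for w in ws:
        fr.append(rem * w)
        rem *= 1.0 - w
    return np.array(fr)


class _BasModel:
    def __init__(self, scheme: GradientScheme):
        self.b = scheme.bvals
        self.g = scheme.directions
        self.sph = scheme.encoding == "spherical"

    def predict(self, params, k):
        s0, d = params[0], params[1]
        ws = params[2:2 + k]
        fr = _stick_fractions(np.clip(ws, 0.0, 1.0)) if k else np.empty(0)
        ball = 1.0 - fr.sum()
        sig = ball * np.exp(-self.b * d)
        for i in range(k):
            th, ph = params[2 + k + 2 * i: 4 + k + 2 * i]
            n = _sph_to_vec(th, ph)
            att = np.exp(-self.b * d * (self.g @ n) ** 2)
            sig = sig + fr[i] * att
        if self.sph.any():
            iso = ball * np.exp(-self.b * d) + fr.sum() * np.exp(-self.b * d / 3.0)
            sig = np.where(self.sph, iso, sig)
        return s0 * sig

    def jacobian(self, params, k):
        """Analytic Jacobian of the predicted signal w.r.t. the parameters."""
        b, g = self.b, self.g
        s0, d = params[0], params[1]
        ws = np.clip(params[2:2 + k], 0.0, 1.0)
        fr = _stick_fractions(ws) if k else np.empty(0)
        ball = 1.0 - fr.sum()
        e0 = np.exp(-b * d)
        esph = np.exp(-b * d / 3.0)
        atts, dth, dph, u2 = [], [], [], []
        for i in range(k):
            th, ph = params[2 + k + 2 * i: 4 + k + 2 * i]
            n = _sph_to_vec(th, ph)
            dn_th = np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph),
                              -np.sin(th)])
            dn_ph = np.array([-np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), 0.0])
            u = g @ n
            a = np.exp(-b * d * u**2)
            atts.append(a)
            u2.append(u**2)
            dth.append(a * (-2 * b * d * u) * (g @ dn_th))
            dph.append(a * (-2 * b * d * u) * (g @ dn_ph))
        sig = ball * e0 + sum(fr[i] * atts[i] for i in range(k))
        jac = np.empty((len(b), 2 + 3 * k))
        jac[:, 0] = sig
        d_d = ball * (-b) * e0 + sum(fr[i] * (-b * u2[i]) * atts[i] for i in range(k))
        jac[:, 1] = s0 * d_d
        for m in range(k):
            one_minus = max(1.0 - ws[m], 1e-12)
            dball = -ball / one_minus
            col = dball * e0
            for i in range(k):
                if i == m:
                    dfi = fr[i] / max(ws[m], 1e-12)
                elif i > m:
                    dfi = -fr[i] / one_minus
                else:
                    continue
                col = col + dfi * atts[i]
            jac[:, 2 + m] = s0 * col
        for i in range(k):
            jac[:, 2 + k + 2 * i] = s0 * fr[i] * dth[i]
            jac[:, 3 + k + 2 * i] = s0 * fr[i] * dph[i]
        if self.sph.any():
            m_sph = self.sph
            f_tot = fr.sum()
            sig_sph = ball * e0 + f_tot * esph
            jac[m_sph, 0] = sig_sph[m_sph]
            jac[m_sph, 1] = s0 * (ball * (-b[m_sph]) * e0[m_sph]
                                  + f_tot * (-b[m_sph] / 3.0) * esph[m_sph])
            for m in range(k):
                one_minus = max(1.0 - ws[m], 1e-12)
                dball = -ball / one_minus
                df_tot = -dball  # fractions sum to 1 - ball
                jac[m_sph, 2 + m] = s0 * (dball * e0[m_sph] + df_tot * esph[m_sph])
            for i in range(k):
                jac[m_sph, 2 + k + 2 * i] = 0.0
                jac[m_sph, 3 + k + 2 * i] = 0.0
        return jac

    def fit(self, y, x0, k, max_nfev=None):
        lo = np.r_[0.0, 1e-4, np.zeros(k), np.full(2 * k, -4 * np.pi)]
        hi = np.r_[np.inf, 4.0, np.ones(k), np.full(2 * k, 4 * np.pi)]
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        res = least_squares(
            lambda p: self.predict(p, k) - y, x0,
            jac=lambda p: self.jacobian(p, k), bounds=(lo, hi),
            max_nfev=max_nfev, xtol=1e-10, ftol=1e-10,
        )
        return res


def _bas_extract(params, k):
    s0, d = params[0], params[1]
    fr = _stick_fractions(np.clip(params[2:2 + k], 0, 1))
    axes = np.array([
        _sph_to_vec(*params[2 + k + 2 * i: 4 + k + 2 * i]) for i in range(k)
    ]) if k else np.empty((0, 3))
    order = np.argsort(-fr)
    return s0, d, fr[order], axes[order]


@dataclass
class BASFit:
    """Ball-and-stick estimates on a voxel grid.

    Per voxel: up to 3 populations sorted by descending signal fraction,
    each with a mean axis and ``n_samples`` bootstrap orientation samples.
    """

    grid_shape: tuple
    voxel_size_mm: np.ndarray
    mask: np.ndarray
    voxel_index: np.ndarray     # (V, 3)
    fractions: np.ndarray       # (V, 3), 0 where absent
    axes: np.ndarray            # (V, 3, 3), NaN where absent
    samples: np.ndarray         # (V, 3, S, 3), NaN where absent
    d: np.ndarray               # (V,)
    s0: np.ndarray              # (V,)
    n_pops: np.ndarray          # (V,)

    def __post_init__(self):
        self._lookup = {tuple(v): i for i, v in enumerate(self.voxel_index)}

    def voxel(self, key):
        """(fractions, samples) of the populations present in one voxel,
        or None if the voxel is outside the fitted mask."""
        i = self._lookup.get(tuple(key))
        if i is None:
            return None
        k = int(self.n_pops[i])
        if k == 0:
            return np.empty(0), np.empty((0, self.samples.shape[2], 3))
        return self.fractions[i, :k], self.samples[i, :k]


def fit_ball_and_stick(
    dwi: DWIVolume,
    max_populations: int = 3,
    n_samples: int = 50,
    f_threshold: float = 0.05,
    seed: int = 0,
    n_restarts: int = 2,
) -> BASFit:
    """Staged nonlinear ball-and-stick fit with bootstrap orientation samples.

    Sticks are added one at a time (k = 1 ... max_populations), each stage
    initialised from the diffusion tensor's eigenvectors plus random
    restarts; stage k is accepted when it improves the BIC and its smallest
    sorted fraction is >= ``f_threshold``. Orientation samples are drawn by
    residual bootstrap: the accepted model is refitted ``n_samples`` times
    to its prediction plus resampled residuals (warm-started, iteration-
    capped), and bootstrap populations are matched to the point-estimate
    populations by axial proximity.
    """
    n_par = lambda k: 2 + 3 * k
    if len(dwi.scheme) < n_par(1) + 1:
        raise ValueError("fewer volumes than ball-and-stick parameters")
    rng = np.random.default_rng(seed)
    model = _BasModel(dwi.scheme)
    dti = fit_dti(dwi)
    nvol = len(dwi.scheme)
    idx = np.argwhere(dwi.mask)
    nv = len(idx)
    s_out = max(n_samples, 1)
    out = BASFit(
        grid_shape=dwi.grid_shape,
        voxel_size_mm=dwi.voxel_size_mm,
        mask=dwi.mask,
        voxel_index=idx,
        fractions=np.zeros((nv, 3)),
        axes=np.full((nv, 3, 3), np.nan),
        samples=np.full((nv, 3, s_out, 3), np.nan),
        d=np.full(nv, np.nan),
        s0=np.full(nv, np.nan),
        n_pops=np.zeros(nv, dtype=int),
    )
    for vi, vx in enumerate(idx):
        t = tuple(vx)
        y = dwi.data[t]
        s0_init = max(float(np.nanmax(y)), 1e-6)
        md = dti.md[t] if np.isfinite(dti.md[t]) else 0.3
        d_init = float(np.clip(md * 1.5, 1e-3, 3.9))
        perfect_rss = 1e-14 * float(np.sum(y**2))
        # k = 0 baseline (pure ball)
        res0 = model.fit(y, np.array([s0_init, d_init]), 0)
        best = dict(k=0, res=res0, bic=_bic(res0, nvol, n_par(0)))
        evecs = [dti.v1[t], None, None]
        if np.all(np.isfinite(dti.tensor[t])):
            ev = np.linalg.eigh(dti.tensor[t])[1]
            evecs = [ev[:, 2], ev[:, 1], ev[:, 0]]
        for k in range(1, max_populations + 1):
            cands = []
            prev = best["res"].x if best["k"] == k - 1 else None
            for trial in range(n_restarts + 1):
                if trial == 0 and evecs[k - 1] is not None and np.all(np.isfinite(evecs[k - 1])):
                    new_axis = evecs[k - 1]
                else:
                    new_axis = rng.standard_normal(3)
                    new_axis /= np.linalg.norm(new_axis)
                th, ph = _vec_to_sph(new_axis)
                if prev is not None and k > 1:
                    # warm start: previous sticks keep their place, the new
                    # stick starts small
                    pw = prev[2:2 + (k - 1)]
                    pang = prev[2 + (k - 1):]
                    x0 = np.r_[prev[0], prev[1], pw, 0.3, pang, th, ph]
                else:
                    angles = []
                    for i in range(k - 1):
                        ev = evecs[min(i, 2)]
                        if ev is None or not np.all(np.isfinite(ev)):
                            ev = rng.standard_normal(3)
                        angles.extend(_vec_to_sph(ev / np.linalg.norm(ev)))
                    x0 = np.r_[s0_init, d_init, np.full(k, 0.4), angles, th, ph]
                try:
                    cands.append(model.fit(y, x0, k))
                except Exception:  # pragma: no cover - optimiser edge case
                    continue
                if cands[-1].cost < perfect_rss:
                    break  # numerically perfect fit; restarts cannot improve
            if not cands:
                break
            res = min(cands, key=lambda r: r.cost)
            bic = _bic(res, nvol, n_par(k))
            _, _, fr_sorted, _ = _bas_extract(res.x, k)
            if bic < best["bic"] and (len(fr_sorted) == 0 or fr_sorted[-1] >= f_threshold):
                best = dict(k=k, res=res, bic=bic)
                if res.cost < perfect_rss:
                    break  # adding sticks cannot improve a perfect fit
            else:
                break
        k = best["k"]
        s0_f, d_f, fr, ax = _bas_extract(best["res"].x, k)
        out.s0[vi], out.d[vi] = s0_f, d_f
        out.n_pops[vi] = k
        out.fractions[vi, :k] = fr
        out.axes[vi, :k] = ax
        if k == 0:
            continue
        if n_samples == 0:
            out.samples[vi, :k, 0] = ax  # mean axes stand in for samples
            continue
        pred = model.predict(best["res"].x, k)
        resid = y - pred
        for s in range(n_samples):
            yb = pred + rng.choice(resid, size=nvol, replace=True)
            yb = np.clip(yb, 0.0, None)
            try:
                rb = model.fit(yb, best["res"].x, k, max_nfev=15)
                _, _, fr_b, ax_b = _bas_extract(rb.x, k)
            except Exception:  # pragma: no cover
                ax_b = ax
            out.samples[vi, :k, s] = _match_axes(ax, ax_b)
    return out


def _bic(res, n, p):
    rss = max(2 * res.cost, 1e-300)
    return n * np.log(rss / n) + p * np.log(n)


def _match_axes(ref: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Permute candidate axes to best match reference axes (axial metric)."""
    k = len(ref)
    if k <= 1 or len(cand) != k:
        return cand[:k] if len(cand) >= k else np.vstack([cand, ref[len(cand):]])
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(ref[i] @ cand[p]) for i, p in enumerate(perm))
        if score > best_score:
            best_score, best_perm = score, perm
    return cand[list(best_perm)]


def orientation_precision(samples: np.ndarray) -> float:
    """Dispersion of orientation samples as a cone half-angle, degrees.

    The mean dyadic tensor <v v^T> over the samples has largest eigenvalue
    lambda_max; the precision statistic is acos(sqrt(lambda_max)): 0 deg for
    identical samples, acos(sqrt(1/3)) ~ 54.7 deg for isotropic samples.
    """
    v = np.asarray(samples, dtype=float)
    v = v[np.all(np.isfinite(v), axis=-1)]
    if len(v) < 2:
        raise ValueError("need at least 2 sample axes")
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    dyad = np.einsum("si,sj->ij", v, v) / len(v)
    lmax = float(np.linalg.eigvalsh(dyad)[-1])
    return float(np.degrees(np.arccos(np.clip(np.sqrt(lmax), -1, 1))))


# ----------------------------------------------------- Ball and Rackets ----

@dataclass
class BARFit:
    grid_shape: tuple
    mask: np.ndarray
    axis: np.ndarray      # (X, Y, Z, 3)
    kappa1: np.ndarray    # (X, Y, Z), kappa1 <= kappa2
    kappa2: np.ndarray
    f: np.ndarray
    d: np.ndarray
    s0: np.ndarray
    converged: np.ndarray


def _bingham_frame(theta, phi, psi):
    mu = _sph_to_vec(theta, phi)
    ref = np.array([0.0, 0.0, 1.0]) if abs(mu[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    a = np.cross(mu, ref)
    a /= np.linalg.norm(a)
    b = np.cross(mu, a)
    e1 = np.cos(psi) * a + np.sin(psi) * b
    e2 = -np.sin(psi) * a + np.cos(psi) * b
    return mu, e1, e2


def bingham_weights(theta, phi, psi, kappa1, kappa2, grid=None):
    """Normalised Bingham FOD weights on the shared symmetric sphere grid.

    Density ~ exp(-kappa1 (u.e1)^2 - kappa2 (u.e2)^2) about the main axis
    mu(theta, phi), with the (e1, e2) pair rotated by psi about mu;
    kappa1 <= kappa2 means dispersion is widest towards e1.
    """
    if grid is None:
        grid = symmetric_sphere_grid(256)
    _, e1, e2 = _bingham_frame(theta, phi, psi)
    w = np.exp(-kappa1 * (grid @ e1) ** 2 - kappa2 * (grid @ e2) ** 2)
    return w / w.sum()


def fit_ball_and_rackets(
    dwi: DWIVolume,
    seed: int = 0,
    kappa_max: float = 500.0,
    n_restarts: int = 2,
) -> BARFit:
    """Fit a single Bingham-dispersed stick plus ball per voxel.

    S / s0 = (1 - f) e^{-b d} + f sum_q w_q e^{-b d (g . u_q)^2}, with
    Bingham weights w_q evaluated by quadrature on the 256-point symmetric
    sphere grid. Returns the FOD main axis, concentrations kappa1 <= kappa2,
    fraction and diffusivity; voxels where no restart converges are flagged.
    """
    grid = symmetric_sphere_grid(256)
    b, g = dwi.scheme.bvals, dwi.scheme.directions
    # canonical-frame quadrature: the grid is rotated into the Bingham frame
    # so the density is always sampled symmetrically about the main axis.
    # First align one grid point with the canonical pole, so a pure stick
    # (kappa -> large) collapses onto the main axis exactly.
    pole = grid[0]
    axis = np.cross(pole, [0.0, 0.0, 1.0])
    s, c = np.linalg.norm(axis), pole[2]
    if s > 1e-12:
        k_ = axis / s
        kx = np.array([[0, -k_[2], k_[1]], [k_[2], 0, -k_[0]], [-k_[1], k_[0], 0]])
        r0 = np.eye(3) + s * kx + (1 - c) * (kx @ kx)
        grid = grid @ r0.T
    gx2, gy2 = grid[:, 0] ** 2, grid[:, 1] ** 2
    dti = fit_dti(dwi)
    rng = np.random.default_rng(seed)
    shape = dwi.grid_shape
    out = BARFit(
        grid_shape=shape, mask=dwi.mask,
        axis=np.full(shape + (3,), np.nan),
        kappa1=np.full(shape, np.nan), kappa2=np.full(shape, np.nan),
        f=np.full(shape, np.nan), d=np.full(shape, np.nan),
        s0=np.full(shape, np.nan),
        converged=np.zeros(shape, dtype=bool),
    )

    def predict(p):
        s0, d, f, th, ph, ps, k1, dk = p
        mu, e1, e2 = _bingham_frame(th, ph, ps)
        w = np.exp(-k1 * gx2 - (k1 + dk) * gy2)
        w /= w.sum()
        u = grid @ np.stack([e1, e2, mu])  # canonical grid -> world
        disp = np.exp(-b[:, None] * d * (g @ u.T) ** 2) @ w
        return s0 * ((1 - f) * np.exp(-b * d) + f * disp)

    lo = [0.0, 1e-4, 0.0, -4 * np.pi, -4 * np.pi, -4 * np.pi, 0.0, 0.0]
    hi = [np.inf, 4.0, 1.0, 4 * np.pi, 4 * np.pi, 4 * np.pi, kappa_max, kappa_max]
    for vx in np.argwhere(dwi.mask):
        t = tuple(vx)
        y = dwi.data[t]
        v1 = dti.v1[t]
        if not np.all(np.isfinite(v1)):
            v1 = np.array([0.0, 0.0, 1.0])
        th0, ph0 = _vec_to_sph(v1)
        md = dti.md[t] if np.isfinite(dti.md[t]) else 0.3
        best = None
        for trial in range(n_restarts + 1):
            if trial == 0:
                x0 = [float(np.nanmax(y)), np.clip(md * 1.5, 1e-3, 3.9),
                      0.6, th0, ph0, 0.1, 5.0, 10.0]
            else:
                rv = rng.standard_normal(3)
                tr, pr = _vec_to_sph(rv / np.linalg.norm(rv))
                x0 = [float(np.nanmax(y)), np.clip(md * 1.5, 1e-3, 3.9),
                      rng.uniform(0.2, 0.9), tr, pr, rng.uniform(0, np.pi),
                      rng.uniform(1, 20), rng.uniform(1, 30)]
            x0 = np.clip(x0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
            try:
                res = least_squares(lambda p: predict(p) - y, x0,
                                    bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
            except Exception:  # pragma: no cover
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < 1e-12 * max(y.max(), 1.0) ** 2 * len(y):
                break
        if best is None:
            continue
        s0_f, d_f, f_f, th, ph, ps, k1, dk = best.x
        mu, _, _ = _bingham_frame(th, ph, ps)
        out.axis[t] = mu
        out.kappa1[t], out.kappa2[t] = k1, k1 + dk
        out.f[t], out.d[t], out.s0[t] = f_f, d_f, s0_f
        out.converged[t] = best.success or best.cost < 1e-6
    return out


# ---------------------------------------------------------------- DIVIDE ----

@dataclass
class DivideMaps:
    md: np.ndarray            # mu1, um^2/ms
    mu2_linear: np.ndarray    # (um^2/ms)^2
    mu2_spherical: np.ndarray
    ufa: np.ndarray
    k_iso: np.ndarray
    k_aniso: np.ndarray
    flagged: np.ndarray


def _powder_shells(dwi: DWIVolume, encoding: str):
    sel = (dwi.scheme.encoding == encoding) & ~dwi.scheme.is_b0
    bs = np.unique(np.round(dwi.scheme.bvals[sel], 3))
    out_b, out_s = [], []
    for b in bs:
        m = sel & (np.abs(dwi.scheme.bvals - b) < 1e-3)
        out_b.append(b)
        out_s.append(dwi.data[..., m].mean(axis=-1))
    return np.asarray(out_b), np.stack(out_s, axis=-1) if out_s else None


def fit_divide(linear_dwi: DWIVolume, spherical_dwi: DWIVolume) -> DivideMaps:
    """Joint gamma-representation fit of powder-averaged multi-b-tensor data.

    Directionally averaged (powder) signals per shell and encoding are
    fitted with the Laplace transform of a gamma diffusivity distribution,

        S(b) / s0 = (1 + b mu2 / mu1)^(-mu1^2 / mu2),

    sharing the mean diffusivity mu1 between encodings but allowing separate
    second moments mu2. The anisotropic variance mu2_linear - mu2_spherical
    gives the microscopic fractional anisotropy

        uFA = sqrt(3/2) [1 + (2/5) (mu1^2 + mu2_sph) /
                          (mu2_lin - mu2_sph)]^(-1/2),

    clamped to [0, 1]; voxels with mu2_linear < mu2_spherical are clamped to
    uFA = 0 and flagged. Isotropic/anisotropic kurtosis components are
    3 mu2 / mu1^2 of the respective variance parts.
    """
    b_lin, s_lin = _powder_shells(linear_dwi, "linear")
    b_sph, s_sph = _powder_shells(spherical_dwi, "spherical")
    if s_lin is None or s_sph is None:
        raise ValueError("need both linear and spherical encoded shells")
    s0_lin = linear_dwi.data[..., linear_dwi.scheme.is_b0].mean(axis=-1)
    shape = s_lin.shape[:-1]
    mask = linear_dwi.mask & spherical_dwi.mask

    md = np.full(shape, np.nan)
    mu2l = np.full(shape, np.nan)
    mu2s = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)

    def gamma_sig(bv, mu1, mu2):
        mu2 = max(mu2, 1e-8)
        return (1.0 + bv * mu2 / mu1) ** (-(mu1**2) / mu2)

    for vx in np.argwhere(mask):
        t = tuple(vx)
        s0 = s0_lin[t]
        if not np.isfinite(s0) or s0 <= 0:
            continue
        yl = s_lin[t] / s0
        ys = s_sph[t] / s0
        mu1_0 = max(-np.log(max(ys[0], 1e-6)) / b_sph[0], 1e-3)

        def resid(p):
            mu1, m2l, m2s, scale = p
            return np.r_[
                scale * gamma_sig(b_lin, mu1, m2l) - yl,
                scale * gamma_sig(b_sph, mu1, m2s) - ys,
            ]

        res = least_squares(
            resid, [mu1_0, 0.3 * mu1_0**2, 1e-4, 1.0],
            bounds=([1e-4, 1e-8, 1e-8, 0.5], [4.0, 16.0, 16.0, 2.0]),
            xtol=1e-12, ftol=1e-12,
        )
        md[t], mu2l[t], mu2s[t] = res.x[0], res.x[1], res.x[2]

    delta = mu2l - mu2s
    flagged = delta < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ufa = np.sqrt(1.5) / np.sqrt(1.0 + 0.4 * (md**2 + mu2s) / np.where(delta > 0, delta, np.nan))
    ufa = np.where(delta <= 0, 0.0, ufa)
    ufa = np.where(np.isnan(md), np.nan, np.clip(ufa, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        k_iso = 3.0 * mu2s / md**2
        k_aniso = 3.0 * np.clip(delta, 0, None) / md**2
    return DivideMaps(md, mu2l, mu2s, ufa, k_iso, k_aniso, flagged)


# -------------------------------------------------------------- T1 (IR) ----

@dataclass
class T1Maps:
    a: np.ndarray
    b: np.ndarray
    t1: np.ndarray
    residual: np.ndarray
    converged: np.ndarray


def fit_t1(signals: np.ndarray, tis: np.ndarray) -> T1Maps:
    """Fit the three-parameter inversion-recovery model per voxel.

    S(TI) = a + b exp(-TI / T1); initialisation scans a log-spaced T1 grid
    (for each grid T1 the model is linear in a and b), and the best grid
    point seeds a bounded nonlinear least-squares refinement. Needs >= 3
    inversion times spanning the recovery.
    """
    tis = np.asarray(tis, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if tis.ndim != 1 or sig.shape[-1] != len(tis) or len(tis) < 3:
        raise ValueError("signals last axis must match >= 3 inversion times")
    flat = sig.reshape(-1, len(tis))
    t1_grid = np.geomspace(max(tis[tis > 0].min(), 1.0), tis.max() * 3, 40)
    basis = np.exp(-tis[None, :] / t1_grid[:, None])  # (G, T)
    a_out = np.empty(flat.shape[0])
    b_out = np.empty(flat.shape[0])
    t1_out = np.empty(flat.shape[0])
    res_out = np.empty(flat.shape[0])
    conv = np.zeros(flat.shape[0], dtype=bool)
    ones = np.ones(len(tis))
    for i, y in enumerate(flat):
        best = None
        for gi, t1 in enumerate(t1_grid):
            design = np.column_stack([ones, basis[gi]])
            coef, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
            rssv = float(rss[0]) if len(rss) else float(
                np.sum((design @ coef - y) ** 2))
            if best is None or rssv < best[0]:
                best = (rssv, coef[0], coef[1], t1)
        _, a0, b0, t10 = best
        res = least_squares(
            lambda p: p[0] + p[1] * np.exp(-tis / p[2]) - y,
            [a0, b0, t10],
            bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12,
        )
        a_out[i], b_out[i], t1_out[i] = res.x
        res_out[i] = float(np.sqrt(2 * res.cost / len(tis)))
        conv[i] = res.success
        if not res.success:
            log.warning("T1 fit did not converge for voxel %d", i)
    shp = sig.shape[:-1]
    return T1Maps(a_out.reshape(shp), b_out.reshape(shp), t1_out.reshape(shp),
                  res_out.reshape(shp), conv.reshape(shp))


def save_bas_samples(bas: BASFit, out_path) -> None:
    """Write ball-and-stick orientation samples as a 5D NIfTI.

    Axis order is (x, y, z, population, sample*3): the last axis interleaves
    the sample axes' components as [s0x, s0y, s0z, s1x, ...]. A JSON sidecar
    (``<out_path>.json``) documents the ordering. Voxels outside the mask or
    populations beyond ``n_pops`` hold NaN.
    """
    import nibabel as nib

    n_s = bas.samples.shape[2]
    vol = np.full(bas.grid_shape + (3, n_s * 3), np.nan, dtype=np.float32)
    for i, vx in enumerate(bas.voxel_index):
        vol[tuple(vx)] = bas.samples[i].reshape(3, n_s * 3)
    affine = np.diag(list(bas.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(out_path))
    sidecar = {
        "axes": ["x", "y", "z", "population", "sample*3"],
        "n_populations": 3,
        "n_samples": int(n_s),
        "last_axis": "sample-major interleaved vector components "
                     "[s0x, s0y, s0z, s1x, ...]",
        "populations_sorted_by": "descending signal fraction",
    }
    with open(str(out_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
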