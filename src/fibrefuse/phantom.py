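"""Synthetic co-registered phantoms: ground-truth fibre fields rendered as
diffusion MRI, PLI stacks, and myelin-stain-like images.

Every downstream stage of the pipeline (PLI inversion, structure-tensor
histology, diffusion model fitting, hybrid fusion) is validated against
phantoms generated here: a single known fibre field — up to three dispersed
fibre populations per voxel plus an isotropic "ball" compartment — rendered
through each modality's forward model with co-registered geometry. The
geometries (coherent bundle, crossing, fanning, undulation) mimic the
canonical white-matter configurations used to stress fibre-orientation
methods.

Units: b-values in ms/um^2, diffusivity in um^2/ms, voxel size in mm,
pixel size in um, angles in degrees at the interfaces.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fusion import PlaneFrame
from .gradients import GradientScheme, write_bvals_bvecs
from .sphere import symmetric_sphere_grid

log = logging.getLogger(__name__)

__all__ = [
    "FibreField",
    "PhantomScene",
    "build_fibre_field",
    "simulate_dwi",
    "simulate_pli_stack",
    "simulate_histology_image",
    "write_phantom_bundle",
]


@dataclass
class FibreField:
    """Ground-truth fibre populations on a voxel grid.

    axes : (X, Y, Z, P, 3) unit fibre axes (axial: v and -v equivalent).
    fractions : (X, Y, Z, P) signal fractions f_i >= 0 with sum <= 1;
        the remainder 1 - sum(f_i) is the isotropic ball fraction.
    kappas : (X, Y, Z, P) Bingham/Watson concentration per population
        (np.inf = no dispersion).
    diffusivity : free diffusivity d in um^2/ms (shared by ball and sticks).
    s0 : baseline (b = 0) signal.
    voxel_size_mm : (3,) voxel edge lengths; grid origin at 0 mm.
    """

    axes: np.ndarray
    fractions: np.ndarray
    kappas: np.ndarray
    diffusivity: float = 0.4
    s0: float = 1.0
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.kappas = np.asarray(self.kappas, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float) * np.ones(3)
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")
        if np.any(self.fractions.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("fractions sum above 1")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        norms = np.linalg.norm(self.axes, axis=-1)
        active = self.fractions > 0
        if np.any(np.abs(norms[active] - 1) > 1e-8):
            raise ValueError("fibre axes must be unit norm")

    @property
    def shape(self):
        return self.axes.shape[:3]

    @property
    def ball_fraction(self) -> np.ndarray:
        return 1.0 - self.fractions.sum(axis=-1)

    def voxel_of_mm(self, points_mm: np.ndarray) -> np.ndarray:
        return np.floor(np.asarray(points_mm) / self.voxel_size_mm).astype(int)


def _axis_from_angle_deg(angle_deg: float) -> np.ndarray:
    """In-plane (x-y) axis at the given angle from +x towards +y."""
    a = np.radians(angle_deg)
    return np.array([np.cos(a), np.sin(a), 0.0])


def build_fibre_field(
    recipe: str,
    shape=(10, 10, 3),
    voxel_size_mm=1.0,
    diffusivity: float = 0.4,
    s0: float = 1.0,
    kappa: float = np.inf,
    **params,
) -> FibreField:
    """Construct a named ground-truth fibre geometry.

    Recipes (all axes lie in the x-y plane unless stated otherwise):

    - ``single``: one coherent population everywhere.
      params: ``angle`` (deg, default 0), ``fraction`` (default 0.7).
    - ``crossing``: two populations at a fixed crossing angle.
      params: ``angle`` (deg between populations, default 90),
      ``fractions`` (pair, default (0.35, 0.35)), ``angle0`` (first axis).
    - ``fanning``: axis angle ramps linearly across the first grid axis.
      params: ``angle_start``/``angle_stop`` (deg, default 0/60),
      ``fraction`` (default 0.7).
    - ``undulation``: angle oscillates sinusoidally along the first axis.
      params: ``amplitude`` (deg, default 30), ``wavelength`` (voxels,
      default 10), ``fraction`` (default 0.7).

    ``kappa`` sets the per-population dispersion (np.inf = coherent).
    """
    shape = tuple(shape)
    nx = shape[0]
    axes = np.zeros(shape + (3, 3))
    fr = np.zeros(shape + (3,))
    kap = np.full(shape + (3,), np.inf)

    if recipe == "single":
        f = float(params.pop("fraction", 0.7))
        ang = float(params.pop("angle", 0.0))
        axes[..., 0, :] = _axis_from_angle_deg(ang)
        fr[..., 0] = f
        kap[..., 0] = kappa
    elif recipe == "crossing":
        ang = float(params.pop("angle", 90.0))
        ang0 = float(params.pop("angle0", 0.0))
        f1, f2 = params.pop("fractions", (0.35, 0.35))
        axes[..., 0, :] = _axis_from_angle_deg(ang0)
        axes[..., 1, :] = _axis_from_angle_deg(ang0 + ang)
        fr[..., 0] = f1
        fr[..., 1] = f2
        kap[..., :2] = kappa
    elif recipe == "fanning":
        f = float(params.pop("fraction", 0.7))
        a0 = float(params.pop("angle_start", 0.0))
        a1 = float(params.pop("angle_stop", 60.0))
        ramp = np.linspace(a0, a1, nx) if nx > 1 else np.array([a0])
        for i, a in enumerate(ramp):
            axes[i, ..., 0, :] = _axis_from_angle_deg(a)
        fr[..., 0] = f
        kap[..., 0] = kappa
    elif recipe == "undulation":
        f = float(params.pop("fraction", 0.7))
        amp = float(params.pop("amplitude", 30.0))
        wav = float(params.pop("wavelength", 10.0))
        for i in range(nx):
            a = amp * np.sin(2 * np.pi * i / wav)
            axes[i, ..., 0, :] = _axis_from_angle_deg(a)
        fr[..., 0] = f
        kap[..., 0] = kappa
    else:
        raise ValueError(f"unknown recipe {recipe!r}")
    if params:
        raise TypeError(f"unknown recipe parameters: {sorted(params)}")
    return FibreField(axes, fr, kap, diffusivity, s0, voxel_size_mm)


@dataclass
class PhantomScene:
    """A fibre field plus the section planes cut through it."""

    field: FibreField
    section_planes: list
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        extent = np.asarray(self.field.shape) * self.field.voxel_size_mm
        for fr in self.section_planes:
            if np.any(fr.origin_mm > extent) or np.any(fr.origin_mm < -1e-9):
                raise ValueError("section plane origin outside the field bounding box")

    @classmethod
    def coronal(cls, field: FibreField, pixel_size_um: float = 4.0,
                thickness_um: float = 50.0, noise_sigma: float = 0.0,
                seed: int = 0, n_planes: int = 1) -> "PhantomScene":
        """Scene with planes normal to z (sections cut along the grid's
        third axis), mid-depth of evenly spaced slabs."""
        extent = np.asarray(field.shape) * field.voxel_size_mm
        planes = []
        for k in range(n_planes):
            z = extent[2] * (k + 0.5) / n_planes
            planes.append(PlaneFrame(
                origin_mm=np.array([0.0, 0.0, z]),
                e1=np.array([1.0, 0.0, 0.0]),
                e2=np.array([0.0, 1.0, 0.0]),
                pixel_size_um=pixel_size_um,
                section_thickness_um=thickness_um,
            ))
        return cls(field, planes, noise_sigma, seed)

    def plane_image_shape(self, plane_index: int) -> tuple:
        fr = self.section_planes[plane_index]
        extent = np.asarray(self.field.shape) * self.field.voxel_size_mm
        ps_mm = fr.pixel_size_um / 1000.0
        w = int(np.floor(extent @ np.abs(fr.e1) / ps_mm))
        h = int(np.floor(extent @ np.abs(fr.e2) / ps_mm))
        return h, w


def _watson_weights(axes: np.ndarray, kappas: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Quadrature weights of a Watson FOD (density ~ exp(kappa (u.mu)^2))
    on the shared symmetric sphere grid. axes (..., 3), kappas (...)."""
    dot2 = np.square(axes @ grid.T)  # (..., Q)
    w = np.exp(kappas[..., None] * (dot2 - 1.0))  # scaled for stability
    return w / w.sum(axis=-1, keepdims=True)


def simulate_dwi(
    field: FibreField,
    scheme: GradientScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Render a fibre field through the ball-and-stick(s) forward model.

    Per voxel, linear-encoded entries follow

        S(g, b) = s0 [ (1 - sum f_i) e^{-b d}
                       + sum_i f_i < e^{-b d (g.n)^2} >_FOD_i ]

    where the FOD average is exact for coherent populations (kappa = inf)
    and evaluated by quadrature over the shared 256-point sphere grid for
    Watson-dispersed populations. Spherical-tensor-encoded entries attenuate
    isotropically with each compartment's mean diffusivity (d for the ball,
    d/3 for a stick). Rician noise of scale ``noise_sigma`` (in s0 units) is
    added to the magnitude signal; ``noise_sigma = 0`` returns the noiseless
    closed form.

    Returns a :class:`fibrefuse.dmri.DWIVolume`.
    """
    from .dmri import DWIVolume

    norms = np.linalg.norm(scheme.directions, axis=1)
    dw = ~scheme.is_b0 & (scheme.encoding == "linear")
    if np.any(np.abs(norms[dw] - 1) > 1e-8):
        raise ValueError("gradient directions must be unit norm")
    b = scheme.bvals
    g = scheme.directions
    d = field.diffusivity
    shape = field.shape
    vox_axes = field.axes.reshape(-1, 3, 3)
    vox_fr = field.fractions.reshape(-1, 3)
    vox_kap = field.kappas.reshape(-1, 3)
    nvox = vox_fr.shape[0]
    nvol = len(scheme)

    linear = scheme.encoding == "linear"
    sig = np.zeros((nvox, nvol))

    ball = 1.0 - vox_fr.sum(axis=1)  # (V,)
    att_ball = np.exp(-b * d)  # (N,)
    sig += ball[:, None] * att_ball[None, :]

    # stick attenuation per population
    dot2 = np.einsum("vpc,nc->vpn", vox_axes, g) ** 2  # (V, P, N)
    coherent_att = np.exp(-b[None, None, :] * d * dot2)
    finite = np.isfinite(vox_kap) & (vox_fr > 0)
    sph_att_stick = np.exp(-b * d / 3.0)  # spherical encoding, any stick

    # coherent fast path for every population, then replace the dispersed ones
    sig += np.einsum("vp,vpn->vn", vox_fr, coherent_att)
    if finite.any():
        grid = symmetric_sphere_grid(256)
        gd2 = np.square(g @ grid.T)  # (N, Q)
        att_grid = np.exp(-b[:, None] * d * gd2)  # (N, Q)
        w = _watson_weights(vox_axes[finite], vox_kap[finite], grid)  # (M, Q)
        disp_att = w @ att_grid.T  # (M, N)
        idx_v, idx_p = np.nonzero(finite)
        np.add.at(
            sig, idx_v,
            vox_fr[idx_v, idx_p, None] * (disp_att - coherent_att[idx_v, idx_p]),
        )

    # spherical encoding: orientationally invariant compartment attenuations
    if np.any(~linear):
        sph = ~linear
        stick_tot = vox_fr.sum(axis=1)
        sig[:, sph] = (
            ball[:, None] * att_ball[None, sph]
            + stick_tot[:, None] * sph_att_stick[None, sph]
        )

    sig *= field.s0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.standard_normal(sig.shape)
        n2 = rng.standard_normal(sig.shape)
        sig = np.sqrt((sig + field.s0 * noise_sigma * n1) ** 2
                      + (field.s0 * noise_sigma * n2) ** 2)
    data = sig.reshape(shape + (nvol,))
    return DWIVolume(data=data, scheme=scheme, voxel_size_mm=field.voxel_size_mm)


def simulate_pli_stack(
    scene: PhantomScene,
    plane_index: int = 0,
    n_frames: int = 9,
    delta_max: float = np.pi / 2,
    transmittance: float = 1.0,
    seed: int | None = None,
    analyser_angles_deg: np.ndarray | None = None,
):
    """Render a section plane as a stack of polarimetric frames.

    Frame k is taken at analyser angle rho_k = k * (180 / n_frames) degrees
    (endpoint excluded so the pi period is sampled exactly once). Each pixel
    samples the fibre content of the voxel it falls in; per-fibre sinusoid
    components mix linearly at the intensity level, weighted by signal
    fraction:

        I(rho) = (I_T / 2) [ 1 + sum_i f_i sin(delta_max cos^2 a_i)
                                        sin(2 rho - 2 phi_i) ]

    with phi_i the in-plane angle and a_i the inclination of population i.
    Through-plane fibres (a = 90 deg) contribute no modulation, and two
    equal perpendicular in-plane populations cancel exactly — the dark bands
    seen between crossing tracts in real polarimetry. Gaussian noise of
    scale ``scene.noise_sigma`` is added.

    Returns a :class:`fibrefuse.pli.PLIStack`.
    """
    from .pli import PLIStack

    if not 0 < delta_max <= np.pi / 2:
        raise ValueError("delta_max must lie in (0, pi/2]")
    frame = scene.section_planes[plane_index]
    h, w = scene.plane_image_shape(plane_index)
    if h < 1 or w < 1:
        raise ValueError("section plane lies outside the field")
    field = scene.field
    e1, e2, nrm = frame.e1, frame.e2, frame.normal

    # per-voxel modulation components
    vox_axes = field.axes.reshape(-1, 3, 3)
    vox_fr = field.fractions.reshape(-1, 3)
    x = vox_axes @ e1
    y = vox_axes @ e2
    z = vox_axes @ nrm
    inpl = np.hypot(x, y)
    phi = np.arctan2(y, x)
    cos2alpha = inpl**2  # axes are unit: cos^2(inclination) = in-plane norm^2
    mod = vox_fr * np.sin(delta_max * cos2alpha)
    cvox = (mod * np.cos(2 * phi)).sum(axis=1)
    svox = (mod * np.sin(2 * phi)).sum(axis=1)

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    vox = frame.pixel_to_voxel(rr.ravel(), cc.ravel(), field.voxel_size_mm)
    vox = np.clip(vox, 0, np.asarray(field.shape) - 1)
    flat = np.ravel_multi_index(tuple(vox.T), field.shape)
    cimg = cvox[flat].reshape(h, w)
    simg = svox[flat].reshape(h, w)

    if analyser_angles_deg is None:
        rho = np.arange(n_frames) * (np.pi / n_frames)
    else:
        rho = np.radians(np.asarray(analyser_angles_deg, dtype=float))
    frames = 0.5 * transmittance * (
        1.0
        + np.sin(2 * rho)[:, None, None] * cimg[None]
        - np.cos(2 * rho)[:, None, None] * simg[None]
    )
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed if seed is None else seed)
        frames = frames + scene.noise_sigma * rng.standard_normal(frames.shape)
        frames = np.clip(frames, 0.0, None)
    return PLIStack(
        frames, np.degrees(rho), frame.pixel_size_um, frame.section_thickness_um
    )


def _von_mises_ppf(kappa: float, n_grid: int = 4097):
    """Numerical inverse CDF of the von Mises(0, kappa) distribution."""
    from scipy.special import i0e

    t = np.linspace(-np.pi, np.pi, n_grid)
    dens = np.exp(kappa * (np.cos(t) - 1.0)) / (2 * np.pi * i0e(kappa))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(t))])
    cdf /= cdf[-1]
    return lambda u: np.interp(u, cdf, t)


def _smooth_uniform_field(shape, corr_length_px, rng):
    """Random field with uniform(0, 1) marginal and the given correlation
    length, via a Gaussian copula (smoothed white noise -> normal CDF)."""
    from scipy import ndimage
    from scipy.special import ndtr

    z = ndimage.gaussian_filter(rng.standard_normal(shape), corr_length_px,
                                mode="wrap")
    z = (z - z.mean()) / max(z.std(), 1e-12)
    return ndtr(z)


def simulate_histology_image(
    scene: PhantomScene,
    plane_index: int = 0,
    fibre_density: float = 0.12,
    seed: int = 0,
    segment_length_px: int = 31,
    segment_depth: float = 0.6,
    jitter_corr_length_px: float = 50.0,
) -> np.ndarray:
    """Render a myelin-stain-like image: dark oriented segments on white.

    Line segments are placed uniformly at random; each segment's orientation
    is the local ground-truth in-plane angle plus dispersion jitter with the
    voxel's axial von Mises marginal (concentration kappa). The jitter is
    spatially correlated over ``jitter_corr_length_px`` — as in tissue,
    where fibre undulation makes nearby fibres share their local deviation —
    realised as a Gaussian-copula random field pushed through the exact von
    Mises inverse CDF. Segments are retained with probability equal to the
    voxel's total fibre fraction, so texture density scales with sum(f_i);
    ``fibre_density`` is the expected fraction of pixels covered by segments
    at sum(f_i) = 1. Returns a grayscale image in [0, 1].
    """
    if fibre_density < 0:
        raise ValueError("fibre density must be non-negative")
    frame = scene.section_planes[plane_index]
    h, w = scene.plane_image_shape(plane_index)
    img = np.ones((h, w))
    if fibre_density == 0:
        return img
    from skimage.draw import line_aa

    field = scene.field
    rng = np.random.default_rng(seed)
    n_segments = int(fibre_density * h * w / segment_length_px)
    half = segment_length_px / 2.0
    e1, e2 = frame.e1, frame.e2
    shape3 = np.asarray(field.shape)
    # one correlated jitter field per population slot
    ufields = [_smooth_uniform_field((h, w), jitter_corr_length_px, rng)
               for _ in range(3)]
    ppf_cache: dict = {}
    for _ in range(n_segments):
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        vox = frame.pixel_to_voxel(np.array([r0]), np.array([c0]),
                                   field.voxel_size_mm)[0]
        vox = np.clip(vox, 0, shape3 - 1)
        fr = field.fractions[tuple(vox)]
        tot = fr.sum()
        if rng.uniform() > tot:
            continue
        p = int(rng.choice(3, p=fr / tot))
        axis = field.axes[tuple(vox)][p]
        ang = np.arctan2(axis @ e2, axis @ e1)
        kap = field.kappas[tuple(vox)][p]
        if np.isfinite(kap):
            # doubled angle ~ vonMises(0, kappa); jitter from the correlated
            # uniform field through the exact inverse CDF
            key = round(float(kap), 6)
            if key not in ppf_cache:
                ppf_cache[key] = _von_mises_ppf(kap)
            u = ufields[p][min(int(r0), h - 1), min(int(c0), w - 1)]
            ang = ang + 0.5 * ppf_cache[key](u)
        dr, dc = np.sin(ang) * half, np.cos(ang) * half
        r1, c1 = int(round(r0 - dr)), int(round(c0 - dc))
        r2, c2 = int(round(r0 + dr)), int(round(c0 + dc))
        r1, r2 = np.clip([r1, r2], 0, h - 1)
        c1, c2 = np.clip([c1, c2], 0, w - 1)
        lr, lc, val = line_aa(r1, c1, r2, c2)
        img[lr, lc] -= segment_depth * val
    img = np.clip(img, 0.0, 1.0)
    if scene.noise_sigma > 0:
        img = np.clip(img + scene.noise_sigma
                      * np.random.default_rng(seed + 1).standard_normal(img.shape),
                      0.0, 1.0)
    return img


def _pixel_to_voxel_affine(frame: PlaneFrame, voxel_size_mm) -> np.ndarray:
    """4x4 affine mapping homogeneous pixel coords (col, row, 0, 1) to
    continuous voxel coordinates."""
    vs = np.asarray(voxel_size_mm, dtype=float) * np.ones(3)
    ps = frame.pixel_size_um / 1000.0
    aff = np.eye(4)
    aff[:3, 0] = ps * frame.e1 / vs
    aff[:3, 1] = ps * frame.e2 / vs
    aff[:3, 2] = frame.normal / vs
    aff[:3, 3] = (frame.origin_mm + 0.5 * ps * (frame.e1 + frame.e2)) / vs
    return aff


def write_phantom_bundle(
    scene: PhantomScene,
    out_dir,
    scheme: GradientScheme | None = None,
    fibre_density: float = 0.2,
) -> dict:
    """Simulate and write the full phantom bundle; returns the manifest.

    Writes the diffusion volume (NIfTI + bvals/bvecs), one multi-page PLI
    TIFF and one histology TIFF per section plane (each with a JSON sidecar
    carrying analyser angles, pixel size and the pixel-to-voxel affine), the
    ground-truth fibre table as TSV, and ``manifest.json`` listing each file
    with its SHA-256 checksum. Re-running with the same scene and seed
    reproduces the files bit for bit.
    """
    import os

    import nibabel as nib
    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    field = scene.field
    if scheme is None:
        from .gradients import generate_directions

        dirs = generate_directions(30, seed=scene.seed)
        dirs = np.vstack([np.zeros(3), dirs])
        bvals = np.r_[0.0, np.full(30, 4.0)]
        scheme = GradientScheme(dirs, bvals)

    files = []

    dwi = simulate_dwi(field, scheme, scene.noise_sigma, scene.seed)
    affine = np.diag(list(field.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(dwi.data.astype(np.float32), affine)
    nib.save(img, os.path.join(out_dir, "dwi.nii"))
    files.append("dwi.nii")
    write_bvals_bvecs(scheme, os.path.join(out_dir, "dwi.bval"),
                      os.path.join(out_dir, "dwi.bvec"))
    files += ["dwi.bval", "dwi.bvec"]

    for k, frame in enumerate(scene.section_planes):
        stack = simulate_pli_stack(scene, k, seed=scene.seed + 101 + k)
        name = f"pli_plane{k}.tif"
        tifffile.imwrite(os.path.join(out_dir, name),
                         stack.frames.astype(np.float32))
        sidecar = {
            "analyser_angles_deg": stack.analyser_angles_deg.tolist(),
            "pixel_size_um": frame.pixel_size_um,
            "section_thickness_um": frame.section_thickness_um,
            "pixel_to_voxel_affine": _pixel_to_voxel_affine(
                frame, field.voxel_size_mm).tolist(),
            "frame": json.loads(frame.to_json()),
        }
        with open(os.path.join(out_dir, name + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
        files += [name, name + ".json"]

        hist = simulate_histology_image(scene, k, fibre_density,
                                        seed=scene.seed + 202 + k)
        hname = f"histology_plane{k}.tif"
        tifffile.imwrite(os.path.join(out_dir, hname), hist.astype(np.float32))
        files.append(hname)

    # ground truth table, one row per voxel and population
    with open(os.path.join(out_dir, "ground_truth.tsv"), "w") as fh:
        fh.write("x\ty\tz\tpopulation\tfraction\tkappa\taxis_x\taxis_y\taxis_z\n")
        for idx in np.ndindex(field.shape):
            for p in range(3):
                f = field.fractions[idx][p]
                if f <= 0:
                    continue
                ax = field.axes[idx][p]
                kap = field.kappas[idx][p]
                fh.write(
                    f"{idx[0]}\t{idx[1]}\t{idx[2]}\t{p}\t{f:.6g}\t{kap:.6g}\t"
                    f"{ax[0]:.8f}\t{ax[1]:.8f}\t{ax[2]:.8f}\n"
                )
    files.append("ground_truth.tsv")

    manifest = {}
    for name in files:
        with open(os.path.join(out_dir, name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
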