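"""Structure-tensor orientation analysis of myelin-stained sections.

A myelin stain (e.g. a silver stain) renders fibres as dark oriented texture
on a bright background. The structure tensor — the Gaussian-smoothed outer
product of the image intensity gradients — gives a per-pixel estimate of the
dominant texture orientation and a coherence measure. Per-pixel orientations
are then pooled over square "superpixels" into 2-degree-binned fibre
orientation distributions (FODs), from which we extract the circular mean,
a concentration parameter kappa of the in-plane Bingham distribution (the
axial von Mises density on doubled angles), and the orientation dispersion
index ODI = 2/pi * atan(1/kappa): 0 for perfectly aligned fibres, 1 for
isotropic dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

log = logging.getLogger(__name__)

KAPPA_MAX = 1.0e4  # cap for the concentration of perfectly aligned data

# nominal resolution of a 40x-digitised silver-stained slide, um per pixel
GALLYAS_PIXEL_SIZE_UM = 0.28
# section thickness the stain is applied to, um
SECTION_THICKNESS_UM = 50.0

__all__ = [
    "OrientationImage",
    "structure_tensor",
    "aggregate_superpixels",
    "fit_axial_concentration",
    "odi_from_kappa",
    "kappa_from_odi",
    "circular_mean_axial",
    "render_orientation_hsv",
]


@dataclass
class OrientationImage:
    """Per-pixel texture orientation.

    angle : degrees in [0, 180), counter-clockwise from the image +x
        (column) axis; axial, i.e. defined modulo 180 degrees.
    coherence : anisotropy of the local structure tensor in [0, 1].
    valid : False where the tensor energy is below the noise floor.
    """

    angle: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray


def structure_tensor(
    image: np.ndarray,
    sigma_deriv: float = 1.0,
    sigma_window: float = 10.0,
    tensor_floor_rel: float = 1e-12,
) -> OrientationImage:
    """Estimate fibre orientation per pixel from oriented image texture.

    Gradients are computed by Gaussian-derivative filtering at scale
    ``sigma_deriv`` (pixels); the tensor components <Ix^2>, <IxIy>, <Iy^2>
    are then averaged with a Gaussian window of scale ``sigma_window``.
    The fibre angle is perpendicular to the dominant gradient direction;
    coherence is (l1 - l2)/(l1 + l2) of the tensor eigenvalues.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # RGB -> luminance
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if min(img.shape) < 6 * sigma_window:
        raise ValueError(
            f"image of shape {img.shape} is smaller than 6*sigma_window "
            f"({6 * sigma_window:g} px)"
        )
    # axis 1 = x (columns), axis 0 = y (rows)
    ix = ndimage.gaussian_filter(img, sigma_deriv, order=(0, 1))
    iy = ndimage.gaussian_filter(img, sigma_deriv, order=(1, 0))
    jxx = ndimage.gaussian_filter(ix * ix, sigma_window)
    jxy = ndimage.gaussian_filter(ix * iy, sigma_window)
    jyy = ndimage.gaussian_filter(iy * iy, sigma_window)

    trace = jxx + jyy
    floor = tensor_floor_rel * max(img.var(), np.finfo(float).tiny)
    valid = trace > floor

    # dominant gradient orientation, then +90 deg for the fibre direction
    angle = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    angle = np.mod(angle + 90.0, 180.0)

    disc = np.sqrt(((jxx - jyy) / 2) ** 2 + jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(valid, 2 * disc / np.where(valid, trace, 1.0), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    angle = np.where(valid, angle, np.nan)
    return OrientationImage(angle=angle, coherence=coherence, valid=valid)


def _bessel_ratio(kappa: float) -> float:
    # I1(k)/I0(k) via exponentially scaled Bessels (overflow-safe)
    return special.i1e(kappa) / special.i0e(kappa)


def fit_axial_concentration(
    angles_deg: np.ndarray,
    weights: np.ndarray | None = None,
    kappa_max: float = KAPPA_MAX,
) -> float:
    """Maximum-likelihood concentration of the axial von Mises density.

    The in-plane restriction of the Bingham distribution is the axial von
    Mises density p(theta) ~ exp(kappa * cos 2(theta - mu)). Its sufficient
    statistic is the mean resultant length Rbar of the doubled angles; the
    MLE solves I1(kappa)/I0(kappa) = Rbar. Perfectly aligned data (Rbar = 1)
    returns ``kappa_max``.
    """
    th = np.radians(np.asarray(angles_deg, dtype=float).ravel())
    if weights is None:
        w = np.ones_like(th)
    else:
        w = np.asarray(weights, dtype=float).ravel()
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all weights are zero")
    z = np.sum(w * np.exp(2j * th)) / wsum
    rbar = float(np.abs(z))
    if rbar <= 1e-12:
        return 0.0
    if rbar >= _bessel_ratio(kappa_max):
        return float(kappa_max)
    return float(optimize.brentq(lambda k: _bessel_ratio(k) - rbar, 1e-12, kappa_max))


def circular_mean_axial(angles_deg, weights=None) -> float:
    """Circular mean of axial data (degrees in [0, 180))."""
    th = np.radians(np.asarray(angles_deg, dtype=float).ravel())
    w = np.ones_like(th) if weights is None else np.asarray(weights, float).ravel()
    z = np.sum(w * np.exp(2j * th))
    return float(np.mod(np.degrees(0.5 * np.angle(z)), 180.0))


def odi_from_kappa(kappa):
    """Orientation dispersion index, ODI = 2/pi * atan(1/kappa).

    kappa = 0 maps to 1 (isotropic dispersion); kappa -> inf maps to 0
    (no dispersion).
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise ValueError("kappa must be non-negative")
    odi = (2.0 / np.pi) * np.arctan2(1.0, k)  # atan(1/k), continuous at k = 0
    return odi if odi.ndim else float(odi)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa` (odi in (0, 1])."""
    o = np.asarray(odi, dtype=float)
    if np.any((o <= 0) | (o > 1)):
        raise ValueError("odi must lie in (0, 1]")
    k = 1.0 / np.tan(np.pi * o / 2.0)
    return k if k.ndim else float(k)


def aggregate_superpixels(
    orient: OrientationImage,
    rgb_image: np.ndarray | None = None,
    window: int = 150,
    pixel_size_um: float | None = None,
    bin_deg: float = 2.0,
    weight_by_coherence: bool = True,
    kappa_max: float = KAPPA_MAX,
) -> pd.DataFrame:
    """Pool per-pixel orientations into superpixel FODs and statistics.

    The image is tiled by ``window`` x ``window`` superpixels (trailing
    partial tiles are kept with their own pixel counts). Per tile the valid
    orientations are combined into a normalised frequency histogram with
    ``bin_deg``-degree bins over [0, 180) — weighted by structure-tensor
    coherence by default — from which the circular mean, the concentration
    kappa and ODI are computed, alongside the mean RGB value.

    Returns a DataFrame with one row per superpixel: centre coordinates in
    pixels (and micrometres if ``pixel_size_um`` is given), n_pixels, valid
    flag, circ_mean_deg, kappa, odi, mean_r/g/b, and the histogram in
    columns ``fod_000`` ... ``fod_178`` (bin lower edges in degrees).
    """
    n_bins = int(round(180.0 / bin_deg))
    h, w = orient.angle.shape
    rows = []
    hist_cols = [f"fod_{int(k * bin_deg):03d}" for k in range(n_bins)]
    edges = np.arange(n_bins + 1) * bin_deg
    for r0 in range(0, h, window):
        for c0 in range(0, w, window):
            r1, c1 = min(r0 + window, h), min(c0 + window, w)
            va = orient.valid[r0:r1, c0:c1]
            ang = orient.angle[r0:r1, c0:c1][va]
            wt = orient.coherence[r0:r1, c0:c1][va] if weight_by_coherence else np.ones(ang.size)
            rec = {
                "row": r0 // window,
                "col": c0 // window,
                "cy_px": (r0 + r1) / 2.0,
                "cx_px": (c0 + c1) / 2.0,
                "n_pixels": int(ang.size),
            }
            if pixel_size_um is not None:
                rec["cy_um"] = rec["cy_px"] * pixel_size_um
                rec["cx_um"] = rec["cx_px"] * pixel_size_um
            if ang.size == 0 or wt.sum() <= 0:
                rec.update(
                    valid=False, circ_mean_deg=np.nan, kappa=np.nan, odi=np.nan,
                    **dict.fromkeys(hist_cols, np.nan),
                )
            else:
                hist, _ = np.histogram(np.mod(ang, 180.0), bins=edges, weights=wt)
                hist = hist / hist.sum()
                kappa = fit_axial_concentration(ang, wt, kappa_max=kappa_max)
                rec.update(
                    valid=True,
                    circ_mean_deg=circular_mean_axial(ang, wt),
                    kappa=kappa,
                    odi=odi_from_kappa(kappa),
                    **dict(zip(hist_cols, hist)),
                )
            if rgb_image is not None:
                tile = np.asarray(rgb_image, dtype=float)[r0:r1, c0:c1]
                if tile.ndim == 2:
                    tile = tile[..., None].repeat(3, axis=-1)
                rec["mean_r"], rec["mean_g"], rec["mean_b"] = tile.reshape(-1, 3).mean(axis=0)
            rows.append(rec)
    return pd.DataFrame(rows)


def render_orientation_hsv(orient: OrientationImage, grey_image: np.ndarray) -> np.ndarray:
    """HSV rendering: hue = angle/180, saturation 1, value = 1 - grey.

    ``grey_image`` is the grey-scale stain intensity in [0, 1] (dark stain =
    dense myelin), so heavily stained regions render bright.
    """
    from skimage.color import hsv2rgb

    hsv = np.zeros(orient.angle.shape + (3,))
    hsv[..., 0] = np.where(orient.valid, orient.angle / 180.0, 0.0)
    hsv[..., 1] = 1.0
    hsv[..., 2] = np.clip(1.0 - np.asarray(grey_image, float), 0.0, 1.0) * orient.valid
    return hsv2rgb(hsv)
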