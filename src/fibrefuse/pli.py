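"""Polarised light imaging: sinusoid inversion and derived maps.

In transmission PLI, a thin brain section sits between crossed polarisers
with a quarter-wave plate; as the analyser rotates through the half-turn,
the intensity at each pixel traces a sinusoid in twice the analyser angle,

    I(rho) = (I_T / 2) * [1 + r * sin(2*rho - 2*phi)],

whose mean gives the transmittance I_T, whose relative amplitude r is the
retardance (set by the myelin content and the fibre inclination), and whose
phase gives the in-plane fibre angle phi. Under the approximation of
constant myelin density, r = sin(delta_max * cos^2(alpha)) also yields a
(qualitative) through-plane inclination angle alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PLIStack",
    "PLIMaps",
    "flatfield_correct",
    "fit_pli_sinusoid",
    "estimate_inclination",
    "render_hsv",
]


@dataclass
class PLIStack:
    """A stack of polarimetric frames.

    frames : (N, H, W) intensities, one frame per analyser angle.
    analyser_angles_deg : strictly increasing angles in [0, 180).
    """

    frames: np.ndarray
    analyser_angles_deg: np.ndarray
    pixel_size_um: float = 4.0
    section_thickness_um: float = 50.0
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.analyser_angles_deg = np.asarray(self.analyser_angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (N, H, W)")
        n = self.frames.shape[0]
        if n < 3:
            raise ValueError("need at least 3 analyser angles")
        if len(self.analyser_angles_deg) != n:
            raise ValueError("angle list length must match frame count")
        a = self.analyser_angles_deg
        # one half-turn is the natural range; a second half-turn duplicates
        # the pi-periodic signal and is tolerated (e.g. 0-360 acquisitions)
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] >= 360:
            raise ValueError("angles must be strictly increasing within [0, 360)")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class PLIMaps:
    """Maps derived from the fitted PLI sinusoid."""

    transmittance: np.ndarray
    retardance: np.ndarray
    angle: np.ndarray          # in-plane angle phi, degrees in [0, 180)
    valid: np.ndarray
    inclination: np.ndarray | None = field(default=None)


def flatfield_correct(stack: PLIStack, background_stack: PLIStack) -> PLIStack:
    """Divide out light-source variation measured without tissue.

    Each frame is divided by its background frame normalised to that frame's
    global mean, so a spatially uniform background leaves the stack
    unchanged. Pixels with zero background are flagged invalid (and set to
    zero).
    """
    bg = background_stack.frames
    if bg.shape != stack.frames.shape:
        raise ValueError("background stack shape must match")
    bad = np.any(bg <= 0, axis=0)
    means = bg.reshape(bg.shape[0], -1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = stack.frames * means[:, None, None] / bg
    corrected[:, bad] = 0.0
    valid = ~bad
    if stack.valid is not None:
        valid = valid & stack.valid
    return PLIStack(
        corrected, stack.analyser_angles_deg, stack.pixel_size_um,
        stack.section_thickness_um, valid=valid,
    )


def fit_pli_sinusoid(stack: PLIStack, r_min: float = 0.01) -> PLIMaps:
    """Fit the PLI sinusoid per pixel and derive transmittance/retardance/angle.

    For equidistant analyser angles covering the pi period the fit reduces
    to exact discrete Fourier components of the 2*rho harmonic:

        a0 = mean(I),  a2 = (2/N) sum I_k cos(2 rho_k),
        b2 = (2/N) sum I_k sin(2 rho_k)

    giving I_T = 2 a0, r = sqrt(a2^2 + b2^2)/a0 and phi = atan2(-a2, b2)/2
    mod 180. Non-equidistant angles fall back to least-squares harmonic
    regression (logged). Pixels with a0 <= 0 or r <= r_min are invalid.
    """
    rho = np.radians(stack.analyser_angles_deg)
    n = len(rho)
    frames = stack.frames
    spacing = np.diff(stack.analyser_angles_deg)
    total = spacing[0] * n if len(spacing) else 0.0
    equidistant = (
        len(spacing) > 0
        and np.allclose(spacing, spacing[0], atol=1e-9)
        and np.isclose(total / 180.0, np.round(total / 180.0), atol=1e-8)
        and np.round(total / 180.0) >= 1
    )
    if equidistant:
        a0 = frames.mean(axis=0)
        c = np.cos(2 * rho)[:, None, None]
        s = np.sin(2 * rho)[:, None, None]
        a2 = (2.0 / n) * (frames * c).sum(axis=0)
        b2 = (2.0 / n) * (frames * s).sum(axis=0)
    else:
        log.info("non-equidistant analyser angles: least-squares harmonic fit")
        design = np.stack([np.ones(n), np.cos(2 * rho), np.sin(2 * rho)], axis=1)
        flat = frames.reshape(n, -1)
        coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
        a0 = coef[0].reshape(frames.shape[1:])
        a2 = coef[1].reshape(frames.shape[1:])
        b2 = coef[2].reshape(frames.shape[1:])

    amp = np.hypot(a2, b2)
    with np.errstate(divide="ignore", invalid="ignore"):
        retardance = np.where(a0 > 0, amp / np.where(a0 > 0, a0, 1.0), 0.0)
    # model I = a0 * (1 + r sin(2 rho - 2 phi)) => a2 = -a0 r sin 2phi,
    # b2 = a0 r cos 2phi
    angle = np.mod(np.degrees(0.5 * np.arctan2(-a2, b2)), 180.0)
    valid = (a0 > 0) & (retardance > r_min)
    if stack.valid is not None:
        valid = valid & stack.valid
    angle = np.where(valid, angle, np.nan)
    return PLIMaps(
        transmittance=2.0 * a0,
        retardance=np.clip(retardance, 0.0, None),
        angle=angle,
        valid=valid,
    )


def estimate_inclination(maps: PLIMaps, delta_max: float = np.pi / 2) -> np.ndarray:
    """Invert retardance into a through-plane inclination angle (degrees).

    Assuming spatially constant myelin content, r = sin(delta_max cos^2 a),
    so a = acos(sqrt(arcsin(r) / delta_max)). Retardance above sin(delta_max)
    is clipped (counted and logged). The result is qualitative: it is useful
    for co-registration contrast, not as a quantitative microscopy metric.
    """
    if not 0 < delta_max <= np.pi / 2:
        raise ValueError("delta_max must lie in (0, pi/2]")
    r = maps.retardance
    rmax = np.sin(delta_max)
    n_clip = int(np.sum(r > rmax))
    if n_clip:
        log.info("clipped %d retardance values above sin(delta_max)", n_clip)
    rc = np.clip(r, 0.0, rmax)
    alpha = np.degrees(np.arccos(np.sqrt(np.arcsin(rc) / delta_max)))
    maps.inclination = alpha
    return alpha


def render_hsv(maps: PLIMaps) -> np.ndarray:
    """Render the fibre maps as RGB: hue = angle, value = retardance.

    hue = phi / 180 (axial colour wheel, so phi and phi + 180 match),
    saturation = 1, value = retardance clipped to [0, 1]; invalid pixels
    are black.
    """
    from skimage.color import hsv2rgb

    hsv = np.zeros(maps.angle.shape + (3,))
    hsv[..., 0] = np.where(maps.valid, np.mod(maps.angle, 180.0) / 180.0, 0.0)
    hsv[..., 1] = 1.0
    hsv[..., 2] = np.clip(maps.retardance, 0.0, 1.0) * maps.valid
    return hsv2rgb(hsv)
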