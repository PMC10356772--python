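"""Evenly spaced points on the sphere and axial-angle utilities.

Diffusion gradient tables and fibre-orientation histograms both need point
sets that are "evenly distributed across the sphere" in the antipodally
symmetric sense (a direction g and its negation -g probe the same diffusion
displacement). The generator here minimises the symmetrised electrostatic
(Coulomb) energy

    E = sum_{i<j} 1/|g_i - g_j| + 1/|g_i + g_j|

by projected repulsion with a monotone (backtracking) line search, the same
construction used by standard scheme-design tools.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "electrostatic_directions",
    "pair_energy",
    "axial_angle_deg",
    "min_axial_angle_deg",
    "symmetric_sphere_grid",
]


def pair_energy(points: np.ndarray) -> float:
    """Antipodally symmetric Coulomb energy of a set of unit vectors."""
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 2:
        return 0.0
    diff = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    summ = np.linalg.norm(p[:, None, :] + p[None, :, :], axis=-1)
    iu = np.triu_indices(p.shape[0], k=1)
    return float(np.sum(1.0 / diff[iu]) + np.sum(1.0 / summ[iu]))


def _repulsion_force(p: np.ndarray) -> np.ndarray:
    d = p[:, None, :] - p[None, :, :]
    s = p[:, None, :] + p[None, :, :]
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    np.fill_diagonal(dn, np.inf)
    np.fill_diagonal(sn, np.inf)
    f = (d / dn[..., None] ** 3).sum(axis=1) + (s / sn[..., None] ** 3).sum(axis=1)
    return f


def electrostatic_directions(
    n: int,
    seed: int = 0,
    iters: int = 200,
    return_energy: bool = False,
):
    """Generate ``n`` unit vectors minimising the antipodal Coulomb energy.

    Parameters
    ----------
    n : number of directions (>= 1).
    seed : seed for the random initial configuration.
    iters : maximum repulsion iterations.
    return_energy : if True, also return the per-iteration energy trace
        (non-increasing by construction).
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    if n == 1:
        p = np.array([[0.0, 0.0, 1.0]])
        return (p, [0.0]) if return_energy else p

    energies = [pair_energy(p)]
    step = 0.1
    for _ in range(iters):
        f = _repulsion_force(p)
        # project force onto the tangent plane of each point
        f -= (f * p).sum(axis=1, keepdims=True) * p
        fmax = np.abs(f).max()
        if fmax == 0:
            break
        trial_step = step
        accepted = False
        for _ in range(30):
            q = p + trial_step * f / fmax
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            e = pair_energy(q)
            if e < energies[-1]:
                p, accepted = q, True
                energies.append(e)
                step = trial_step * 1.2
                break
            trial_step *= 0.5
        if not accepted:
            break
    if return_energy:
        return p, energies
    return p


def axial_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in degrees between axes (orientations modulo sign), in [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dot = np.abs((u * v).sum(axis=-1))
    norm = np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    return np.degrees(np.arccos(np.clip(dot / norm, -1.0, 1.0)))


def min_axial_angle_deg(points: np.ndarray) -> float:
    """Smallest pairwise axial angle of a point set, degrees."""
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("need at least two directions")
    dot = np.abs(p @ p.T)
    np.fill_diagonal(dot, 0.0)
    return float(np.degrees(np.arccos(np.clip(dot.max(), -1.0, 1.0))))


@lru_cache(maxsize=8)
def _cached_grid(n_points: int, seed: int) -> np.ndarray:
    if n_points % 2:
        raise ValueError("symmetric grid needs an even number of points")
    half = electrostatic_directions(n_points // 2, seed=seed, iters=400)
    return np.vstack([half, -half])


def symmetric_sphere_grid(n_points: int = 256) -> np.ndarray:
    """Antipodally paired sphere grid: point k and point k + n/2 are negatives.

    The first half is an electrostatically relaxed hemisphere representative
    set; the second half mirrors it, so the grid is exactly symmetric under
    v -> -v. Used both as the orientation-histogram support and as the
    quadrature grid for Bingham/Watson integrals (uniform weights 4*pi/n).
    """
    return _cached_grid(n_points, 20200420).copy()
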