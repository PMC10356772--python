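"""Diffusion gradient schemes: generation, ordering, batching, text I/O.

A good HARDI gradient table has three properties: (i) the full set of
directions covers the sphere evenly; (ii) every prefix of the acquisition
order also covers the sphere evenly, so an interrupted scan still yields a
usable shell; and (iii) nearly colinear directions are not played out in
close succession, which spreads gradient-coil heating. The three operations
here produce tables with exactly those properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sphere import (
    axial_angle_deg,
    electrostatic_directions,
    min_axial_angle_deg,
)

log = logging.getLogger(__name__)

B0_THRESHOLD = 0.05  # ms/um^2; entries at or below count as b ~ 0

__all__ = [
    "GradientScheme",
    "generate_directions",
    "order_incremental",
    "interleave_batches",
    "coverage_metric",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]


@dataclass
class GradientScheme:
    """A diffusion acquisition scheme.

    directions : (N, 3) unit vectors (zero rows allowed for b ~ 0 entries);
        axial convention, g and -g are equivalent.
    bvals : (N,) b-values in ms/um^2.
    encoding : (N,) array of "linear" or "spherical" b-tensor shapes.
    """

    directions: np.ndarray
    bvals: np.ndarray
    encoding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        if self.encoding is None:
            self.encoding = np.full(len(self.bvals), "linear", dtype=object)
        else:
            self.encoding = np.asarray(self.encoding, dtype=object)
        if len(self.directions) != len(self.bvals) or len(self.bvals) != len(self.encoding):
            raise ValueError("directions, bvals and encoding lengths differ")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.directions, axis=1)
        dw = ~self.is_b0 & (self.encoding == "linear")
        if np.any(np.abs(norms[dw] - 1.0) > 1e-8):
            raise ValueError("diffusion-weighted gradient directions must be unit norm")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def shell(self, b: float, encoding: str = "linear", tol: float = 0.5) -> "GradientScheme":
        """Extract the entries of one shell (by b-value and encoding)."""
        sel = (np.abs(self.bvals - b) < tol) & (self.encoding == encoding)
        return GradientScheme(self.directions[sel], self.bvals[sel], self.encoding[sel])


def generate_directions(n: int, seed: int = 0, iters: int = 200) -> np.ndarray:
    """Evenly distribute ``n`` directions on the sphere.

    Minimises the antipodally symmetric electrostatic energy by iterative
    repulsion; the final configuration's energy is available through
    :func:`fibrefuse.sphere.pair_energy`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return electrostatic_directions(n, seed=seed, iters=iters)


def coverage_metric(directions: np.ndarray) -> float:
    """Coverage of a direction set: minimal pairwise axial angle, degrees.

    Larger is better; duplicated directions give 0.
    """
    return min_axial_angle_deg(directions)


def order_incremental(directions: np.ndarray) -> np.ndarray:
    """Order directions so every prefix covers the sphere well.

    Greedy maximin: start from the first direction, then repeatedly append
    the direction whose minimal axial angle to all already-chosen directions
    is largest. Returns the permutation (indices into the input).
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(d)
    if n < 1:
        raise ValueError("need at least one direction")
    chosen = [0]
    remaining = list(range(1, n))
    # min axial angle from each remaining direction to the chosen set
    dot = np.abs(d @ d.T)
    ang = np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))
    min_ang = ang[:, 0].copy()
    while remaining:
        best = max(remaining, key=lambda i: (min_ang[i], -i))
        if min_ang[best] < 1e-9:
            log.warning("duplicate directions in input; tie-broken by input order")
        chosen.append(best)
        remaining.remove(best)
        min_ang = np.minimum(min_ang, ang[:, best])
    return np.asarray(chosen, dtype=int)


def _order_batch(dirs: np.ndarray, min_succ_angle: float) -> np.ndarray:
    """Permute one batch so consecutive axial angles are >= min_succ_angle
    where feasible; otherwise maximise the minimum consecutive angle greedily."""
    n = len(dirs)
    order = [0]
    remaining = list(range(1, n))
    while remaining:
        prev = dirs[order[-1]]
        angles = axial_angle_deg(dirs[remaining], prev)
        nxt = remaining[int(np.argmax(angles))]
        if np.max(angles) < min_succ_angle:
            log.warning(
                "no remaining direction at >= %.1f deg from the previous one; "
                "taking the farthest (%.2f deg)", min_succ_angle, float(np.max(angles)),
            )
        order.append(nxt)
        remaining.remove(nxt)
    return np.asarray(order, dtype=int)


def interleave_batches(
    scheme: GradientScheme,
    batch_size: int = 25,
    min_succ_angle: float = 10.0,
) -> GradientScheme:
    """Insert a b ~ 0 volume before each batch and de-colinearise each batch.

    The input scheme is assumed already incrementally ordered. Output length
    is ``n + ceil(n / batch_size)``: one non-diffusion-weighted entry leads
    each batch of at most ``batch_size`` weighted entries, and entries within
    a batch are permuted so consecutive axial angles stay >= ``min_succ_angle``
    when feasible.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    dirs, bvals, enc = [], [], []
    n = len(scheme)
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        batch = scheme.directions[start:stop]
        perm = _order_batch(batch, min_succ_angle)
        dirs.append(np.zeros((1, 3)))
        bvals.append([0.0])
        enc.append(["linear"])
        dirs.append(batch[perm])
        bvals.append(scheme.bvals[start:stop][perm])
        enc.append(list(scheme.encoding[start:stop][perm]))
    return GradientScheme(
        np.vstack(dirs), np.concatenate(bvals), np.concatenate(enc)
    )


def write_bvals_bvecs(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """Write the one-row bvals / three-row bvecs text dialect."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.directions.T, fmt="%.8f")


def read_bvals_bvecs(bvals_path, bvecs_path, encoding=None) -> GradientScheme:
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvecs_path))
    if bvecs.shape != (len(bvals), 3):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("bvecs shape does not match bvals length")
    return GradientScheme(bvecs, bvals, encoding)
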