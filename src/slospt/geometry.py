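"""Spherocylinder geometry under periodic boundary conditions.

Rods are line segments of length ``L`` (the cylinder axis) dressed with a
hard-core diameter ``D``; two rods overlap iff the minimum distance between
their axis segments is smaller than ``D`` (strictly — contact at exactly
``D`` counts as non-overlapping).  The pair interaction of charged rods
depends only on that minimum axis distance ``x`` and on ``sin(theta)`` of the
crossing angle, so those two descriptors are what this module computes.

The minimum segment–segment distance uses the clamped closest-point
algorithm: solve the unconstrained two-parameter minimisation, then clamp
and re-minimise alternately in both orders, keeping the closer candidate —
the minimum of this convex quadratic over a box always lies on one of the
paths explored.  Periodic boundaries are handled by the minimum-image convention on
the center–center separation, which is valid as long as every box edge
exceeds twice the interaction reach ``L + range`` (enforced by callers).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RodConfiguration",
    "PairDescriptor",
    "pair_descriptor",
    "segment_pair_metrics",
    "min_segment_distance",
    "hard_overlap",
    "neighbor_candidates",
    "distances_to_rod",
    "distances_to_trial",
    "write_snapshot",
    "read_snapshot",
]


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap center–center displacement(s) into the nearest periodic image."""
    return delta - box * np.round(delta / box)


def segment_pair_metrics(r12: np.ndarray, u1: np.ndarray, u2: np.ndarray,
                         half_length: float) -> tuple[np.ndarray, np.ndarray]:
    """Minimum distance and |sin theta| for segment pairs, vectorised.

    Parameters
    ----------
    r12
        Center separation c2 - c1, already minimum-imaged, shape (..., 3).
    u1, u2
        Unit axis vectors, broadcastable to the shape of ``r12``.
    half_length
        Half the cylinder length, L/2.

    Returns
    -------
    x, sin_theta : ndarray
        Minimum distance between the two segments, and |u1 x u2|.
    """
    r12 = np.asarray(r12, dtype=float)
    u1 = np.broadcast_to(np.asarray(u1, dtype=float), r12.shape)
    u2 = np.broadcast_to(np.asarray(u2, dtype=float), r12.shape)
    h = half_length
    b = np.einsum("...i,...i->...", u1, u2)
    e1 = np.einsum("...i,...i->...", r12, u1)
    e2 = np.einsum("...i,...i->...", r12, u2)
    denom = 1.0 - b * b
    parallel = denom < 1e-12
    safe = np.where(parallel, 1.0, denom)
    # unconstrained closest points: p1 = c1 + s u1, p2 = c2 + t u2
    s0 = np.where(parallel, np.clip(e1, -h, h), (e1 - b * e2) / safe)
    t0 = np.where(parallel, np.clip(s0 * b - e2, -h, h), (b * e1 - e2) / safe)
    # If the unconstrained solution falls outside the parameter box the
    # minimum lies on an edge: clamp one parameter, re-minimise the other,
    # clamp, re-minimise the first.  Doing this in both orders and keeping
    # the closer pair covers every edge case of the convex problem.
    sa = np.clip(s0, -h, h)
    ta = np.clip(sa * b - e2, -h, h)
    sa = np.clip(e1 + ta * b, -h, h)
    ta = np.clip(sa * b - e2, -h, h)
    sa = np.clip(e1 + ta * b, -h, h)
    tb = np.clip(t0, -h, h)
    sb = np.clip(e1 + tb * b, -h, h)
    tb = np.clip(sb * b - e2, -h, h)
    sb = np.clip(e1 + tb * b, -h, h)
    tb = np.clip(sb * b - e2, -h, h)
    sep_a = r12 + ta[..., None] * u2 - sa[..., None] * u1
    sep_b = r12 + tb[..., None] * u2 - sb[..., None] * u1
    xa = np.einsum("...i,...i->...", sep_a, sep_a)
    xb = np.einsum("...i,...i->...", sep_b, sep_b)
    x = np.sqrt(np.minimum(xa, xb))
    cross = np.cross(u1, u2)
    sin_theta = np.sqrt(np.einsum("...i,...i->...", cross, cross))
    return x, np.clip(sin_theta, 0.0, 1.0)


def min_segment_distance(center1, u1, center2, u2, L: float, box=None
                         ) -> tuple[float, float]:
    """Minimum axis distance and crossing angle for a single rod pair.

    Applies the minimum-image convention to the center separation when a
    ``box`` is given.  Returns ``(x, theta)`` with ``theta`` in [0, pi/2]
    (only sin theta enters the interaction; the acute-angle convention is
    free of orientation-vector sign ambiguity).
    """
    r12 = np.asarray(center2, dtype=float) - np.asarray(center1, dtype=float)
    if box is not None:
        r12 = minimum_image(r12, np.asarray(box, dtype=float))
    x, sin_theta = segment_pair_metrics(r12, u1, u2, L / 2.0)
    return float(x), float(np.arcsin(np.clip(sin_theta, 0.0, 1.0)))


def hard_overlap(x, D: float):
    """Hard-core overlap criterion: strictly x < D (contact is allowed)."""
    if D <= 0:
        raise ValueError("D must be strictly positive")
    return np.asarray(x) < D


@dataclass(frozen=True)
class PairDescriptor:
    """Interaction-relevant descriptors of one rod pair."""

    x: float
    theta: float
    within_cutoff: bool


def pair_descriptor(config: "RodConfiguration", i: int, j: int,
                    cutoff: float) -> PairDescriptor:
    """Minimum axis distance and crossing angle for rods i and j."""
    x, theta = min_segment_distance(config.centers[i], config.orientations[i],
                                    config.centers[j], config.orientations[j],
                                    config.L, config.box)
    return PairDescriptor(x=x, theta=theta, within_cutoff=x < cutoff)


@dataclass
class RodConfiguration:
    """Periodic box of identical spherocylinders.

    ``centers`` are wrapped into [0, box) on construction; ``orientations``
    must be unit vectors.  Every box edge must exceed L + D so a rod can
    never overlap its own periodic image.
    """

    box: np.ndarray
    centers: np.ndarray
    orientations: np.ndarray
    L: float
    D: float

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        if self.centers.shape != self.orientations.shape:
            raise ValueError("centers and orientations must have matching shapes")
        if self.L < 0 or self.D <= 0:
            raise ValueError("rod geometry requires L >= 0 and D > 0")
        if np.any(self.box <= self.L + self.D):
            raise ValueError(
                f"box edges {self.box} must exceed L + D = {self.L + self.D} "
                "so rods cannot overlap their own images")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("orientation vectors must be unit-norm to 1e-12")
        self.centers = np.mod(self.centers, self.box)

    @property
    def n_rods(self) -> int:
        return self.centers.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "RodConfiguration":
        return RodConfiguration(self.box.copy(), self.centers.copy(),
                                self.orientations.copy(), self.L, self.D)


def distances_to_rod(config: RodConfiguration, i: int,
                     center=None, orientation=None,
                     exclude_self: bool = True,
                     indices: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis distances and sin theta from rod ``i`` (optionally displaced) to others.

    ``center``/``orientation`` override rod i's stored state (used for trial
    moves).  Returns ``(indices, x, sin_theta)`` over the compared rods.
    """
    c = config.centers[i] if center is None else np.asarray(center, dtype=float)
    u = config.orientations[i] if orientation is None else np.asarray(orientation, dtype=float)
    if indices is None:
        indices = np.arange(config.n_rods)
    if exclude_self:
        indices = indices[indices != i]
    r12 = minimum_image(config.centers[indices] - c, config.box)
    x, sin_theta = segment_pair_metrics(r12, u, config.orientations[indices],
                                        config.L / 2.0)
    return indices, x, sin_theta


def distances_to_trial(config: RodConfiguration, centers: np.ndarray,
                       orientations: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Axis distances between each of M trial rods and all N system rods.

    Returns arrays of shape (M, N): minimum distances and sin theta.
    Vectorised over the full M x N pair set.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    orientations = np.asarray(orientations, dtype=float).reshape(-1, 3)
    r12 = config.centers[None, :, :] - centers[:, None, :]
    r12 = minimum_image(r12, config.box)
    u1 = np.broadcast_to(orientations[:, None, :], r12.shape)
    u2 = np.broadcast_to(config.orientations[None, :, :], r12.shape)
    return segment_pair_metrics(r12, u1, u2, config.L / 2.0)


def neighbor_candidates(config: RodConfiguration, i: int, reach: float,
                        center=None) -> np.ndarray:
    """Indices of rods whose axis distance to rod ``i`` could be below ``reach``.

    Prunes on the center–center distance: the axes of two rods can approach
    no closer than |r_centers| - L, so any rod with |r_centers| >= reach + L
    is provably outside range.  Falls back to all other rods when the pruning
    radius exceeds half the smallest box edge (minimum image no longer bounds
    the true distance there).  ``center`` overrides rod i's stored position —
    required when pruning around a trial move destination.
    """
    if reach < config.D:
        raise ValueError("reach must cover at least the hard-core diameter")
    others = np.arange(config.n_rods)
    others = others[others != i]
    radius = reach + config.L
    if radius >= np.min(config.box) / 2.0:
        return others
    c = config.centers[i] if center is None else np.asarray(center, dtype=float)
    r12 = minimum_image(config.centers[others] - c, config.box)
    keep = np.einsum("ij,ij->i", r12, r12) < radius * radius
    return others[keep]


# --- snapshot text format -------------------------------------------------
# line 1: "slospt-snapshot N"
# line 2: "box bx by bz"
# line 3: "rod L D"
# then N lines: x y z ux uy uz  (full double precision)

def write_snapshot(config: RodConfiguration, path_or_buf) -> None:
    """Write a configuration as plain text (round-trips bit-exactly)."""
    buf = io.StringIO()
    buf.write(f"slospt-snapshot {config.n_rods}\n")
    buf.write("box " + " ".join(repr(float(v)) for v in config.box) + "\n")
    buf.write(f"rod {config.L!r} {config.D!r}\n")
    for c, u in zip(config.centers, config.orientations):
        buf.write(" ".join(repr(float(v)) for v in (*c, *u)) + "\n")
    data = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(data)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(data)


def read_snapshot(path_or_buf) -> RodConfiguration:
    """Read a configuration written by :func:`write_snapshot`."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split()
    if header[0] != "slospt-snapshot":
        raise ValueError("not a slospt snapshot file")
    n = int(header[1])
    box = np.array([float(v) for v in lines[1].split()[1:4]])
    _, L, D = lines[2].split()
    body = np.array([[float(v) for v in line.split()] for line in lines[3:3 + n]])
    return RodConfiguration(box=box, centers=body[:, :3], orientations=body[:, 3:6],
                            L=float(L), D=float(D))
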