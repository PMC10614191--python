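"""Metropolis Monte Carlo of charged hard spherocylinders.

The rods carry a hard core of diameter ``D`` plus the screened double-layer
repulsion

    beta U(x, theta) = A' exp(-kappa (x - D)) / sin(theta),   x >= D,

which in a simulation is truncated at ``d_c`` and shifted so the potential is
exactly zero at the cutoff (continuity avoids a spurious pressure from the
discontinuity).  ``x`` is the minimum axis–axis distance and ``theta`` the
crossing angle; the 1/sin(theta) divergence for parallel rods is floored at a
configurable ``sin_theta_floor`` so that a fully aligned starting
configuration has finite energy and can relax.

Sampling is plain Metropolis with single-particle translations and
rotations, acceptance tuned into a target window during equilibration only.
The production protocol mirrors how dense rod fluids are prepared: start
from a dense, perfectly aligned (trivially overlap-free) state, let it relax
to the isotropic fluid, then expand the box stepwise to reach lower volume
fractions, re-equilibrating after every expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import RodConfiguration, distances_to_rod, neighbor_candidates

__all__ = [
    "EnergyModel",
    "SimulationConfig",
    "SimulationState",
    "pair_energy",
    "truncated_shifted_energy",
    "rod_energy",
    "total_energy",
    "metropolis_sweep",
    "tune_move_sizes",
    "equilibrate",
    "sample_snapshots",
    "expansion_protocol",
    "aligned_configuration",
    "random_configuration",
    "nematic_order",
]


@dataclass(frozen=True)
class EnergyModel:
    """Truncated-shifted screened repulsion between rod axes.

    ``A_prime = 0`` turns the model into pure hard spherocylinders (the
    cutoff is then irrelevant).  Energies are in units of k_B T.
    """

    A_prime: float
    kappa: float
    D: float
    d_c: float
    sin_theta_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.A_prime < 0:
            raise ValueError("A_prime must be non-negative")
        if self.D <= 0 or self.kappa <= 0:
            raise ValueError("kappa and D must be strictly positive")
        if not self.d_c > self.D:
            raise ValueError("cutoff d_c must exceed the hard diameter D")
        if not 0 < self.sin_theta_floor <= 1:
            raise ValueError("sin_theta_floor must lie in (0, 1]")

    @property
    def reach(self) -> float:
        """Axis distance beyond which the pair energy is exactly zero."""
        return self.D if self.A_prime == 0.0 else self.d_c


def pair_energy(x, sin_theta, model: EnergyModel):
    """Bare (untruncated) reduced pair energy; +inf on hard-core violation."""
    x = np.asarray(x, dtype=float)
    s = np.maximum(np.asarray(sin_theta, dtype=float), model.sin_theta_floor)
    u = model.A_prime * np.exp(-model.kappa * (x - model.D)) / s
    return np.where(x < model.D, np.inf, u)


def truncated_shifted_energy(x, sin_theta, model: EnergyModel):
    """Pair energy truncated at d_c and shifted to vanish there.

    u_c(x, theta) = u(x, theta) - u(d_c, theta) for x < d_c, else 0; the
    shift is evaluated at the same crossing angle, so the potential is
    continuous in x for every theta.  Hard-core violations stay infinite.
    """
    x = np.asarray(x, dtype=float)
    s = np.maximum(np.asarray(sin_theta, dtype=float), model.sin_theta_floor)
    core = np.exp(-model.kappa * (x - model.D)) - math.exp(-model.kappa * (model.d_c - model.D))
    u = model.A_prime * core / s
    u = np.where(x >= model.d_c, 0.0, u)
    return np.where(x < model.D, np.inf, u)


def rod_energy(config: RodConfiguration, i: int, model: EnergyModel,
               center=None, orientation=None) -> float:
    """Total interaction energy of rod ``i`` (optionally displaced) with all others."""
    idx = neighbor_candidates(config, i, model.reach, center=center)
    _, x, s = distances_to_rod(config, i, center=center, orientation=orientation,
                               indices=idx, exclude_self=False)
    if np.any(x < model.D):
        return math.inf
    if model.A_prime == 0.0:
        return 0.0
    return float(np.sum(truncated_shifted_energy(x, s, model)))


def total_energy(config: RodConfiguration, model: EnergyModel) -> float:
    """Full pairwise energy of the configuration (half-sum over rods)."""
    e = 0.0
    for i in range(config.n_rods):
        ei = rod_energy(config, i, model)
        if math.isinf(ei):
            return math.inf
        e += ei
    return 0.5 * e


@dataclass
class SimulationConfig:
    """Run-control parameters for the Metropolis simulation."""

    n_rods: int = 1352
    L_over_D: float = 10.0
    max_disp: float = 0.3
    max_rot: float = 0.3
    max_disp_cap: float = 2.0
    max_rot_cap: float = 1.0
    reorient_fraction: float = 0.2   # fraction of rotation trials that draw a
                                     # fresh uniform orientation (symmetric
                                     # proposal; decorrelates global order)
    target_acceptance: tuple[float, float] = (0.3, 0.4)
    n_sweeps_equil: int = 400
    n_sweeps_sample: int = 200
    snapshot_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_acceptance
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("target_acceptance must be an interval inside (0, 1)")
        if self.n_rods <= 0 or self.n_sweeps_equil < 0 or self.n_sweeps_sample <= 0:
            raise ValueError("counts must be positive")


@dataclass
class SimulationState:
    """Mutable simulation state: configuration, cached energy, statistics."""

    configuration: RodConfiguration
    energy: float
    sweep_index: int = 0
    accepted: dict = field(default_factory=lambda: {"translate": 0, "rotate": 0, "reorient": 0})
    attempted: dict = field(default_factory=lambda: {"translate": 0, "rotate": 0, "reorient": 0})

    def acceptance_ratio(self, move_type: str | None = None) -> float:
        if move_type is None:
            att = sum(self.attempted.values())
            acc = sum(self.accepted.values())
        else:
            att, acc = self.attempted[move_type], self.accepted[move_type]
        return acc / att if att else float("nan")

    def reset_stats(self) -> None:
        for k in self.accepted:
            self.accepted[k] = 0
            self.attempted[k] = 0

    def audit_energy(self, model: EnergyModel, tol: float = 1e-8) -> None:
        """Verify the incrementally updated energy against a full recomputation."""
        full = total_energy(self.configuration, model)
        if not math.isfinite(full):
            raise RuntimeError(
                "full energy recomputation is non-finite: the configuration "
                "contains a hard-core overlap that legal moves cannot produce")
        if abs(full - self.energy) > tol * max(1.0, abs(full)):
            raise RuntimeError(
                f"energy cache drifted: cached {self.energy!r}, recomputed {full!r}")
        self.energy = full


def _random_rotation(u: np.ndarray, max_angle: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """Rotate unit vector ``u`` by a uniform angle in [0, max_angle) about a
    random axis perpendicular to nothing in particular (any random axis)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    c, s = math.cos(angle), math.sin(angle)
    new = (u * c + np.cross(axis, u) * s + axis * np.dot(axis, u) * (1.0 - c))
    return new / np.linalg.norm(new)


def metropolis_sweep(state: SimulationState, sim: SimulationConfig,
                     model: EnergyModel, rng: np.random.Generator) -> SimulationState:
    """One sweep = N single-particle trial moves (translation or rotation).

    Moves are accepted with probability min(1, e^{-dU}); any hard-core
    overlap rejects outright.  The cached total energy is updated
    incrementally.
    """
    config = state.configuration
    n = config.n_rods
    for _ in range(n):
        i = int(rng.integers(n))
        if rng.random() < 0.5:
            kind = "translate"
            new_c = config.centers[i] + rng.uniform(-sim.max_disp, sim.max_disp, 3)
            new_c = np.mod(new_c, config.box)
            new_u = config.orientations[i]
        elif rng.random() < sim.reorient_fraction:
            kind = "reorient"
            new_c = config.centers[i]
            new_u = rng.normal(size=3)
            new_u /= np.linalg.norm(new_u)
        else:
            kind = "rotate"
            new_c = config.centers[i]
            new_u = _random_rotation(config.orientations[i], sim.max_rot, rng)
        state.attempted[kind] += 1
        e_new = rod_energy(config, i, model, center=new_c, orientation=new_u)
        if math.isinf(e_new):
            continue
        e_old = 0.0 if model.A_prime == 0.0 else rod_energy(config, i, model)
        du = e_new - e_old
        if du <= 0.0 or rng.random() < math.exp(-du):
            config.centers[i] = new_c
            config.orientations[i] = new_u
            state.energy += du
            state.accepted[kind] += 1
    state.sweep_index += 1
    return state


def tune_move_sizes(state: SimulationState, sim: SimulationConfig) -> bool:
    """Nudge move sizes toward the target acceptance window.

    Returns True when the sizes saturated at their caps (dilute systems
    accept nearly everything no matter how large the moves).  Only call
    during equilibration: changing move sizes mid-sampling breaks detailed
    balance.
    """
    lo, hi = sim.target_acceptance
    saturated = False
    for kind, attr, cap in (("translate", "max_disp", sim.max_disp_cap),
                            ("rotate", "max_rot", sim.max_rot_cap)):
        ratio = state.acceptance_ratio(kind)
        if math.isnan(ratio):
            continue
        size = getattr(sim, attr)
        if ratio > hi:
            new = min(size * 1.25, cap)
            if new == cap and size == cap:
                saturated = True
            setattr(sim, attr, new)
        elif ratio < lo:
            setattr(sim, attr, max(size * 0.8, 1e-4))
    state.reset_stats()
    return saturated


def nematic_order(orientations: np.ndarray) -> float:
    """Largest eigenvalue S of the nematic Q-tensor (1 = aligned, ~0 = isotropic)."""
    u = np.asarray(orientations, dtype=float)
    q = 1.5 * (u.T @ u) / len(u) - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(q)[-1])


def aligned_configuration(n_rods: int, L: float, D: float, phi: float,
                          ) -> RodConfiguration:
    """Overlap-free aligned start: rods on a lattice, all axes along z.

    The box is cubic with volume set by the requested hard-core volume
    fraction ``phi``; rods sit on a simple tetragonal lattice stretched along
    the common axis so neighbouring rods cannot touch.
    """
    v_r = math.pi * D**2 * L / 4.0 + math.pi * D**3 / 6.0
    volume = n_rods * v_r / phi
    box = np.full(3, volume ** (1.0 / 3.0))
    # lattice: nz layers along z, nx*ny columns; scale to fill the box
    nz = max(1, int(round((n_rods * (D / (L + D)) ** 2) ** (1.0 / 3.0))))
    while True:
        nxy = math.ceil(math.sqrt(n_rods / nz))
        if nxy * nxy * nz >= n_rods:
            break
        nz += 1
    xs = (np.arange(nxy) + 0.5) / nxy * box[0]
    ys = (np.arange(nxy) + 0.5) / nxy * box[1]
    zs = (np.arange(nz) + 0.5) / nz * box[2]
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    centers = grid[:n_rods]
    orientations = np.tile([0.0, 0.0, 1.0], (n_rods, 1))
    return RodConfiguration(box=box, centers=centers, orientations=orientations,
                            L=L, D=D)


def random_configuration(n_rods: int, L: float, D: float, phi: float,
                         rng: np.random.Generator,
                         max_attempts: int = 2_000_000) -> RodConfiguration:
    """Overlap-free isotropic start by random sequential insertion.

    Rods are inserted one by one at uniform positions/orientations, rejecting
    hard overlaps.  Feasible well below the sequential-packing limit; a dense
    system that cannot be filled within ``max_attempts`` raises.  The result
    is isotropic but not equilibrated — follow with :func:`equilibrate`.
    """
    from .geometry import segment_pair_metrics, minimum_image
    v_r = math.pi * D**2 * L / 4.0 + math.pi * D**3 / 6.0
    volume = n_rods * v_r / phi
    box = np.full(3, volume ** (1.0 / 3.0))
    if np.any(box <= L + D):
        raise ValueError("box too small for this (n_rods, phi) combination")
    centers = np.empty((n_rods, 3))
    orients = np.empty((n_rods, 3))
    placed = 0
    attempts = 0
    batch = 512
    while placed < n_rods:
        if attempts > max_attempts:
            raise RuntimeError(
                f"random packing stalled at {placed}/{n_rods} rods (phi={phi})")
        m = batch
        attempts += m
        c_try = rng.uniform(0.0, 1.0, (m, 3)) * box
        u_try = rng.normal(size=(m, 3))
        u_try /= np.linalg.norm(u_try, axis=1, keepdims=True)
        if placed:
            r12 = minimum_image(centers[None, :placed, :] - c_try[:, None, :], box)
            x, _ = segment_pair_metrics(
                r12, u_try[:, None, :], orients[None, :placed, :], L / 2.0)
            ok = np.all(x >= D, axis=1)
        else:
            ok = np.ones(m, dtype=bool)
        # the batch filter is stale once rods from the same batch are added,
        # so every surviving candidate is rechecked against the full set
        for j in np.flatnonzero(ok):
            if placed:
                r_new = minimum_image(centers[:placed] - c_try[j], box)
                x, _ = segment_pair_metrics(r_new, u_try[j], orients[:placed], L / 2.0)
                if np.any(x < D):
                    continue
            centers[placed] = c_try[j]
            orients[placed] = u_try[j]
            placed += 1
            if placed == n_rods:
                break
    return RodConfiguration(box=box, centers=centers[:n_rods],
                            orientations=orients[:n_rods], L=L, D=D)


def equilibrate(state: SimulationState, sim: SimulationConfig, model: EnergyModel,
                rng: np.random.Generator, n_sweeps: int | None = None,
                tune_interval: int = 20, audit_interval: int = 200,
                ) -> SimulationState:
    """Run equilibration sweeps with periodic acceptance tuning and energy audits."""
    n_sweeps = sim.n_sweeps_equil if n_sweeps is None else n_sweeps
    for k in range(n_sweeps):
        metropolis_sweep(state, sim, model, rng)
        if (k + 1) % tune_interval == 0:
            tune_move_sizes(state, sim)
        if (k + 1) % audit_interval == 0:
            state.audit_energy(model)
    state.reset_stats()
    return state


def sample_snapshots(state: SimulationState, sim: SimulationConfig,
                     model: EnergyModel, rng: np.random.Generator,
                     ) -> list[RodConfiguration]:
    """Production run: fixed move sizes, snapshots every ``snapshot_interval`` sweeps."""
    snaps = []
    for k in range(sim.n_sweeps_sample):
        metropolis_sweep(state, sim, model, rng)
        if (k + 1) % sim.snapshot_interval == 0:
            snaps.append(state.configuration.copy())
    state.audit_energy(model)
    return snaps


def _rescale(config: RodConfiguration, new_box: np.ndarray) -> RodConfiguration:
    """Affine box rescaling: fractional center coordinates and orientations kept."""
    frac = config.centers / config.box
    return RodConfiguration(box=new_box, centers=frac * new_box,
                            orientations=config.orientations.copy(),
                            L=config.L, D=config.D)


def expansion_protocol(sim: SimulationConfig, model: EnergyModel,
                       phi_schedule, rng: np.random.Generator,
                       relax_sweeps: int | None = None,
                       order_threshold: float = 0.35,
                       ):
    """Aligned dense start, relax, then expand stepwise through ``phi_schedule``.

    ``phi_schedule`` must be strictly decreasing hard-core volume fractions.
    Yields ``(phi, state, snapshots)`` per density.  After the initial
    relaxation the nematic order parameter must have decayed below
    ``order_threshold``; otherwise the aligned start is considered frozen and
    a RuntimeError is raised.
    """
    phis = list(phi_schedule)
    if any(b >= a for a, b in zip(phis, phis[1:])):
        raise ValueError("phi_schedule must be strictly decreasing")
    L = sim.L_over_D * model.D
    config = aligned_configuration(sim.n_rods, L, model.D, phis[0])
    if np.any(config.box < 2.0 * (L + model.reach)):
        raise ValueError(
            f"box {config.box} too small for minimum-image interactions with "
            f"reach L + d_c = {L + model.reach}; reduce d_c or the density, "
            "or use more rods")
    state = SimulationState(configuration=config,
                            energy=total_energy(config, model))
    first = True
    for phi in phis:
        if not first:
            volume = sim.n_rods * (math.pi * model.D**2 * L / 4.0
                                   + math.pi * model.D**3 / 6.0) / phi
            state.configuration = _rescale(state.configuration,
                                           np.full(3, volume ** (1.0 / 3.0)))
            state.energy = total_energy(state.configuration, model)
        n_relax = (relax_sweeps if (first and relax_sweeps is not None)
                   else sim.n_sweeps_equil)
        equilibrate(state, sim, model, rng, n_sweeps=n_relax)
        if first:
            s_order = nematic_order(state.configuration.orientations)
            if s_order > order_threshold:
                raise RuntimeError(
                    f"aligned start failed to relax: nematic order {s_order:.3f} "
                    f"after {n_relax} sweeps (frozen or too dense)")
            first = False
        snaps = sample_snapshots(state, sim, model, rng)
        yield phi, state, snaps
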