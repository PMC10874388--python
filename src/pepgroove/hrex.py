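"""Hamiltonian replica exchange with selective torsion scaling, on toy systems.

The protocol accelerates side-chain conformational transitions by running
parallel replicas in which the *selected* torsion potential terms are
multiplied by a scale factor

    U'_torsion = scale_n * U_torsion = (T0 / Tn) * U_torsion,

so replica ``n`` samples a softened Hamiltonian whose torsion barriers
correspond to an effective temperature ``Tn`` while every replica runs at
the base temperature ``T0``.  Neighbouring replicas periodically attempt a
configuration swap under the standard Hamiltonian-exchange Metropolis
criterion, and the scale-1.0 replica provides the analysis trajectory.

The sampler here is Metropolis Monte Carlo on torsion coordinates of toy
periodic-cosine systems; the replica-exchange logic (scaling scheme,
ladder, exchange test, analysis of replica 1) is the faithfully implemented
part.  Energies are in kT units at T0 throughout (beta absorbed), so the
Metropolis tests use the energies directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LadderError
from .rotamers import DihedralSeries, wrap_angle

DEFAULT_PROPOSAL_WIDTH = 0.6  # rad


# ---------------------------------------------------------------------------
# System
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionTerm:
    """Periodic torsion term ``k * (1 + cos(m*phi - phase))`` in kT units.

    A multiplicity-2 term is the double well used by the toy systems; the
    ``scalable`` flag marks terms subject to the replica scale factor.
    """

    coord: int
    k: float
    multiplicity: int = 1
    phase: float = 0.0
    scalable: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("torsion amplitude must be >= 0")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def energy(self, phi: float) -> float:
        return self.k * (1.0 + math.cos(self.multiplicity * phi - self.phase))


@dataclass(frozen=True)
class Coupling:
    """Pairwise coupling ``J * cos(phi_i - phi_j)``; never scaled."""

    i: int
    j: int
    jconst: float

    def energy(self, phi_i: float, phi_j: float) -> float:
        return self.jconst * math.cos(phi_i - phi_j)


@dataclass
class ToyTorsionSystem:
    """Torsion-chain system: angles on (-pi, pi], cosine terms, couplings."""

    n_coords: int
    terms: list[TorsionTerm]
    couplings: list[Coupling] = field(default_factory=list)
    t0: float = 300.0

    def __post_init__(self):
        for t in self.terms:
            if not 0 <= t.coord < self.n_coords:
                raise ValueError(f"term coordinate {t.coord} out of range")
        for c in self.couplings:
            if not (0 <= c.i < self.n_coords and 0 <= c.j < self.n_coords):
                raise ValueError("coupling coordinate out of range")
        # Per-coordinate lookup for local-energy evaluation.
        self._terms_by_coord: list[list[TorsionTerm]] = [
            [] for _ in range(self.n_coords)
        ]
        for t in self.terms:
            self._terms_by_coord[t.coord].append(t)
        self._couplings_by_coord: list[list[Coupling]] = [
            [] for _ in range(self.n_coords)
        ]
        for c in self.couplings:
            self._couplings_by_coord[c.i].append(c)
            self._couplings_by_coord[c.j].append(c)

    def energy_parts(self, config: np.ndarray) -> tuple[float, float, float]:
        """(scalable torsion sum, fixed torsion sum, coupling sum) in kT."""
        scal = fixed = 0.0
        for t in self.terms:
            e = t.energy(float(config[t.coord]))
            if t.scalable:
                scal += e
            else:
                fixed += e
        coup = sum(c.energy(float(config[c.i]), float(config[c.j])) for c in self.couplings)
        return scal, fixed, coup

    def local_energy(self, config: np.ndarray, coord: int, scale: float) -> float:
        """Energy of the terms touching one coordinate, with scaling applied."""
        e = 0.0
        for t in self._terms_by_coord[coord]:
            et = t.energy(float(config[coord]))
            e += scale * et if t.scalable else et
        for c in self._couplings_by_coord[coord]:
            e += c.energy(float(config[c.i]), float(config[c.j]))
        return e


def scaled_energy(system: ToyTorsionSystem, config: np.ndarray, scale: float) -> float:
    """Total energy with the scalable torsion sum multiplied by ``scale`` (kT).

    Non-scalable torsion terms and couplings enter unscaled.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    scal, fixed, coup = system.energy_parts(np.asarray(config, float))
    return fixed + scale * scal + coup


# ---------------------------------------------------------------------------
# Ladder
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLadder:
    """Effective-temperature ladder and the torsion scale factors T0/Tk."""

    n: int
    t0: float
    tn: float
    temperatures: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        assert abs(self.scales[0] - 1.0) < 1e-12
        assert np.all(np.diff(self.scales) < 0)


def build_ladder(
    n: int, t0: float, tn: float, spacing: str = "geometric"
) -> ReplicaLadder:
    """Replica ladder from T0 to Tn with scale_k = T0 / T_k.

    Geometric spacing (default): ``T_k = T0 * (Tn/T0)**((k-1)/(n-1))``,
    giving a constant temperature ratio between neighbours; linear spacing
    interpolates the temperatures directly.
    """
    if n < 2:
        raise LadderError("need at least 2 replicas")
    if not (tn > t0 > 0):
        raise LadderError("require Tn > T0 > 0")
    k = np.arange(n)
    if spacing == "geometric":
        temps = t0 * (tn / t0) ** (k / (n - 1))
    elif spacing == "linear":
        temps = t0 + (tn - t0) * k / (n - 1)
    else:
        raise LadderError(f"unknown spacing {spacing!r}")
    scales = t0 / temps
    scales[0] = 1.0
    return ReplicaLadder(n=n, t0=t0, tn=tn, temperatures=temps, scales=scales)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class ReplicaState:
    """Configuration of one replica; all replicas share the base temperature."""

    index: int
    angles: np.ndarray
    rng: np.random.Generator

    def __post_init__(self):
        self.angles = wrap_angle(np.asarray(self.angles, float)).copy()
        if self.angles.ndim == 0:
            self.angles = self.angles.reshape(1)


def mc_sweep(
    system: ToyTorsionSystem,
    state: ReplicaState,
    scale: float,
    n_moves: int,
    width: float = DEFAULT_PROPOSAL_WIDTH,
) -> tuple[ReplicaState, int]:
    """Metropolis single-angle Gaussian-perturbation moves on the scaled energy.

    Each move perturbs one uniformly chosen coordinate; the symmetric
    proposal and the Metropolis test against the scale-weighted energy give
    detailed balance at T0.  Returns the updated state and the acceptance
    count.
    """
    if width <= 0:
        raise ValueError("proposal width must be positive")
    rng = state.rng
    angles = state.angles
    coords = rng.integers(0, system.n_coords, size=n_moves)
    steps = rng.normal(0.0, width, size=n_moves)
    unifs = rng.random(size=n_moves)
    accepted = 0
    for c, step, u in zip(coords, steps, unifs):
        c = int(c)
        old = angles[c]
        e_old = system.local_energy(angles, c, scale)
        angles[c] = wrap_angle(old + step)
        e_new = system.local_energy(angles, c, scale)
        delta = e_new - e_old
        if delta <= 0.0 or u < math.exp(-delta):
            accepted += 1
        else:
            angles[c] = old
    return state, accepted


def exchange_attempt(
    state_i: ReplicaState,
    state_j: ReplicaState,
    system: ToyTorsionSystem,
    ladder: ReplicaLadder,
    rng: np.random.Generator,
    allow_nonneighbor: bool = False,
) -> bool:
    """Metropolis swap of two replicas' configurations.

    Accepted with probability ``min(1, exp(-Delta))`` where
    ``Delta = U_i(x_j) + U_j(x_i) - U_i(x_i) - U_j(x_j)`` and ``U_k`` is the
    scale_k-scaled potential in kT at T0 -- the unique criterion preserving
    each replica's Boltzmann distribution.  On acceptance the configurations
    swap.  Non-neighbour pairs raise unless ``allow_nonneighbor``.
    """
    i, j = state_i.index, state_j.index
    if abs(i - j) != 1 and not allow_nonneighbor:
        raise ValueError(f"replicas {i} and {j} are not ladder neighbours")
    si, sj = float(ladder.scales[i]), float(ladder.scales[j])
    xi, xj = state_i.angles, state_j.angles
    delta = (
        scaled_energy(system, xj, si)
        + scaled_energy(system, xi, sj)
        - scaled_energy(system, xi, si)
        - scaled_energy(system, xj, sj)
    )
    accept = delta <= 0.0 or rng.random() < math.exp(-delta)
    if accept:
        state_i.angles, state_j.angles = xj, xi
    return bool(accept)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class HrexResult:
    """Trajectories and exchange statistics of a replica-exchange run."""

    angles: np.ndarray  # (n_replicas, n_recorded, n_coords)
    ladder: ReplicaLadder
    attempts: np.ndarray  # per neighbour pair (n-1,)
    accepts: np.ndarray
    round_trips: int
    seed: int

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)

    def series(self, replica: int = 0) -> DihedralSeries:
        """Per-frame angle series of one replica (replica 0 = the analysis one)."""
        arr = self.angles[replica]
        scale = float(self.ladder.scales[replica])
        cols = {"frame": np.arange(arr.shape[0]), "traj": f"scale={scale:.4f}"}
        for c in range(arr.shape[1]):
            cols[f"phi{c}"] = arr[:, c]
        return DihedralSeries(pd.DataFrame(cols))


def run_hrex(
    system: ToyTorsionSystem,
    ladder: ReplicaLadder,
    n_sweeps: int,
    moves_per_sweep: int,
    exchange_interval: int,
    seed: int,
    width: float = DEFAULT_PROPOSAL_WIDTH,
) -> HrexResult:
    """Replica-exchange run with alternating even/odd neighbour exchanges.

    Every ``exchange_interval`` sweeps all even (then, next time, all odd)
    neighbour pairs attempt a swap; the fixed attempt interval mirrors the
    fixed-time exchange schedule of production replica-exchange protocols.
    The full run is a pure function of (system, ladder, schedule, seed):
    each replica draws from its own counter-derived stream, so results do
    not depend on execution order.  Replica 0 (scale 1.0) is the analysis
    trajectory.
    """
    if n_sweeps < 1 or moves_per_sweep < 1 or exchange_interval < 1:
        raise ValueError("n_sweeps, moves_per_sweep, exchange_interval must be >= 1")
    n_rep = ladder.n
    streams = np.random.SeedSequence(seed).spawn(n_rep + 1)
    exch_rng = np.random.default_rng(streams[-1])
    states = []
    for r in range(n_rep):
        rng = np.random.default_rng(streams[r])
        init = rng.uniform(-math.pi, math.pi, size=system.n_coords)
        states.append(ReplicaState(index=r, angles=init, rng=rng))

    angles_out = np.empty((n_rep, n_sweeps, system.n_coords))
    attempts = np.zeros(n_rep - 1, dtype=int) if n_rep > 1 else np.zeros(0, dtype=int)
    accepts = np.zeros_like(attempts)

    # Walker bookkeeping for round-trip counting: walker w sits at ladder
    # position pos[w]; a round trip is bottom -> top -> bottom.
    walker_at = list(range(n_rep))  # replica index -> walker id
    walker_phase = [0] * n_rep  # 0: heading to top, 1: heading back down
    round_trips = 0
    exchange_block = 0

    for sweep in range(n_sweeps):
        for r, st in enumerate(states):
            mc_sweep(system, st, float(ladder.scales[r]), moves_per_sweep, width)
        if n_rep > 1 and (sweep + 1) % exchange_interval == 0:
            parity = exchange_block % 2
            exchange_block += 1
            for k in range(parity, n_rep - 1, 2):
                attempts[k] += 1
                if exchange_attempt(states[k], states[k + 1], system, ladder, exch_rng):
                    accepts[k] += 1
                    walker_at[k], walker_at[k + 1] = walker_at[k + 1], walker_at[k]
            for pos in (0, n_rep - 1):
                w = walker_at[pos]
                if pos == n_rep - 1 and walker_phase[w] == 0:
                    walker_phase[w] = 1
                elif pos == 0 and walker_phase[w] == 1:
                    walker_phase[w] = 0
                    round_trips += 1
        for r, st in enumerate(states):
            angles_out[r, sweep] = st.angles

    return HrexResult(
        angles=angles_out,
        ladder=ladder,
        attempts=attempts,
        accepts=accepts,
        round_trips=round_trips,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reference densities for validation
# ---------------------------------------------------------------------------

def boltzmann_density_1d(
    system: ToyTorsionSystem, scale: float = 1.0, grid_size: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised Boltzmann density of a 1-coordinate system by quadrature."""
    if system.n_coords != 1:
        raise ValueError("quadrature reference only for 1-coordinate systems")
    grid = np.linspace(-math.pi, math.pi, grid_size, endpoint=False)
    u = np.array([scaled_energy(system, np.array([g]), scale) for g in grid])
    w = np.exp(-(u - u.min()))
    dens = w / (w.sum() * (grid[1] - grid[0]))
    return grid, dens
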