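"""Cell dynamics: motility, pairwise forces, contact guidance, division.

Cells are overdamped point particles on a periodic square domain.  Each
time step a cell feels a Gaussian random-motility kick, capped
Lennard-Jones pairwise forces from its neighbours (short-range volume
exclusion, mid-range adhesion), and the combined vector is reoriented --
but never rescaled -- by the contact-guidance operator built from the
local collagen orientation tensor.  Crowding-limited proliferation adds
daughters at half a cell diameter from their parent.

All randomness flows through a single generator per simulation.  Within
a step the draws occur in a fixed, documented order: (1) the 2N motility
normals (cell-major), (2) one kick angle per coincident pair in
ascending (i, j) order, (3) N division uniforms, (4) one division angle
per divider in ascending cell id.  Identical seed + config therefore
reproduces trajectories bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .fibre_field import FibreField, normalise_tensor

log = logging.getLogger(__name__)

#: separations below this (um) count as coincident cells
COINCIDENT_TOL = 1e-9


@dataclass
class ModelParams:
    """The model parameter vector.

    Units: lengths in um, times in minutes, rates in 1/min.

    D : cell diffusion coefficient (um^2/min)
    epsilon : magnitude of pairwise interactions (um^2/min)
    sigma : cell diameter (um)
    F0 : cap on the repulsive pairwise force (um/min)
    r_max : range of cell-cell interactions; defaults to 3*sigma
    Delta0 : mean cell-cycle length absent crowding (min); may be inf
    lambda_bar : collagen area fraction of half-maximal contact guidance
    gamma : steepness of the guidance switch around lambda_bar
    m : velocity-averaging (memory) window for fibre secretion (min)
    s, d : collagen secretion / degradation rates per cell (1/min)
    dt : numerical time step (min)
    delta : fibre-grid spacing (um)
    domain_length : side of the periodic square domain (um)
    T_final : simulation end time (min)
    seed : RNG seed
    guidance_normalisation : 'spectral' (default) or 'trace' convention
        for the normalised tensor entering the guidance operator
    """

    D: float = 0.3
    epsilon: float = 0.1
    sigma: float = 12.0
    F0: float = 2.4
    r_max: float | None = None
    Delta0: float = 1440.0
    lambda_bar: float = 0.4
    gamma: float = 10.0
    m: float = 300.0
    s: float = 0.0
    d: float = 0.0
    dt: float = 1.0
    delta: float = 2.0
    domain_length: float = 360.0
    T_final: float = 3600.0
    seed: int = 0
    guidance_normalisation: str = "spectral"

    def __post_init__(self):
        if self.r_max is None:
            self.r_max = 3.0 * self.sigma
        self.validate()

    def validate(self) -> None:
        for name in ("sigma", "F0", "r_max", "Delta0", "gamma", "m",
                     "dt", "delta", "domain_length", "T_final"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"parameter {name} must be positive, got {v}")
        for name in ("D", "epsilon", "s", "d"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(
                    f"parameter {name} must be non-negative, got {v}")
        if not 0.0 <= self.lambda_bar <= 1.0:
            raise ValueError(f"lambda_bar must lie in [0, 1], "
                             f"got {self.lambda_bar}")
        if self.d * self.dt >= 1.0:
            raise ValueError(
                f"degradation step unstable: d*dt = {self.d * self.dt} >= 1")
        n = self.domain_length / self.delta
        if abs(n - round(n)) > 1e-9:
            raise ValueError("domain_length must be a multiple of delta")
        if self.guidance_normalisation not in ("spectral", "trace"):
            raise ValueError(
                f"unknown guidance normalisation "
                f"{self.guidance_normalisation!r}")

    @property
    def repulsion_range(self) -> float:
        """Separation below which the pairwise force is repulsive."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(round(self.domain_length / self.delta))
        return n, n


@dataclass
class VelocityMemory:
    """Endpoints of each cell's velocity-averaging window.

    ``start`` holds the unwrapped position at ``max(t - m, birth)``,
    ``end`` the unwrapped position at ``t``, and ``window_min`` the
    realised window length ``m' = min(m, t - birth)`` in minutes.
    """

    start: np.ndarray
    end: np.ndarray
    window_min: np.ndarray


class CellPopulation:
    """Positions, unwrapped displacement histories and ids of N(t) cells.

    Wrapped positions live in ``[0, L)^2``; unwrapped positions accumulate
    true displacements (for velocity averaging and MSD) and differ from
    the wrapped ones by integer multiples of the domain length per axis.
    A ring buffer of unwrapped positions covers the memory window.
    """

    def __init__(self, positions, domain_length: float,
                 history_steps: int = 300, dt: float = 1.0,
                 birth_time: float = 0.0):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        self.domain_length = float(domain_length)
        self.dt = float(dt)
        n = len(positions)
        self.positions = np.mod(positions, self.domain_length)
        self.unwrapped = self.positions.copy()
        self.ids = np.arange(n, dtype=np.int64)
        self.birth_times = np.full(n, float(birth_time))
        self.birth_steps = np.zeros(n, dtype=np.int64)
        self._hist_len = int(history_steps) + 1
        cap = max(2 * n, 64)
        self._hist = np.empty((self._hist_len, cap, 2))
        self._hist[:, :n] = self.unwrapped[None, :, :]
        self.step_index = 0

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def time_min(self) -> float:
        return self.step_index * self.dt

    def _grow(self, need: int) -> None:
        cap = self._hist.shape[1]
        if need <= cap:
            return
        new = np.empty((self._hist_len, max(need, 2 * cap), 2))
        new[:, :cap] = self._hist
        self._hist = new

    def advance(self, new_unwrapped: np.ndarray) -> None:
        """Record a synchronous position update for all cells."""
        if not np.all(np.isfinite(new_unwrapped)):
            raise FloatingPointError("non-finite cell positions")
        self.unwrapped = np.asarray(new_unwrapped, dtype=float)
        self.positions = np.mod(self.unwrapped, self.domain_length)
        self.step_index += 1
        self._hist[self.step_index % self._hist_len, :self.n] = self.unwrapped

    def add_cells(self, unwrapped_positions: np.ndarray) -> None:
        """Append daughters at the current step.

        Their history is initialised at the birth position so the
        averaging window never reaches before birth.
        """
        new = np.atleast_2d(np.asarray(unwrapped_positions, dtype=float))
        k = len(new)
        if k == 0:
            return
        n0 = self.n
        self._grow(n0 + k)
        self.ids = np.concatenate([
            self.ids, np.arange(self.ids[-1] + 1 if n0 else 0,
                                (self.ids[-1] + 1 if n0 else 0) + k)])
        self.birth_times = np.concatenate(
            [self.birth_times, np.full(k, self.time_min)])
        self.birth_steps = np.concatenate(
            [self.birth_steps, np.full(k, self.step_index, dtype=np.int64)])
        self.unwrapped = np.vstack([self.unwrapped, new])
        self.positions = np.vstack(
            [self.positions, np.mod(new, self.domain_length)])
        self._hist[:, n0:n0 + k] = new[None, :, :]

    def velocity_memory(self, m: float) -> VelocityMemory:
        """Window endpoints for the averaged secretion direction.

        The window is truncated at each cell's birth: ``m' = min(m,
        t - birth)``, so young daughters average over their whole life.
        """
        m_steps = int(round(m / self.dt))
        if m_steps + 1 > self._hist_len:
            raise ValueError("memory window exceeds the history buffer")
        lag = np.minimum(m_steps, self.step_index - self.birth_steps)
        idx = (self.step_index - lag) % self._hist_len
        start = self._hist[idx, np.arange(self.n)]
        return VelocityMemory(start=start.copy(), end=self.unwrapped.copy(),
                              window_min=lag * self.dt)

    def to_dataframe(self, time_min: float | None = None):
        import pandas as pd

        t = self.time_min if time_min is None else time_min
        return pd.DataFrame({
            "time_min": np.full(self.n, float(t)),
            "cell_id": self.ids,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "x_unwrapped_um": self.unwrapped[:, 0],
            "y_unwrapped_um": self.unwrapped[:, 1],
            "birth_time_min": self.birth_times,
        })


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def min_image_displacement(xi, xj, domain_length: float):
    """Shortest periodic separation ``xi - xj``, componentwise in
    ``[-L/2, L/2)``."""
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    half = 0.5 * domain_length
    return np.mod(d + half, domain_length) - half


def lj_force_magnitude(r, params: ModelParams):
    """Capped Lennard-Jones force magnitude (um/min).

    ``min{24 eps sigma^6 [2 sigma^6 / r^13 - 1/r^7], F0}`` for
    ``0 < r <= r_max`` and 0 beyond.  Positive values repel, negative
    values (adhesion) are untouched by the cap.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("pair separation must be positive")
    s6 = params.sigma ** 6
    mag = 24.0 * params.epsilon * s6 * (2.0 * s6 / arr ** 13 - 1.0 / arr ** 7)
    f = np.minimum(mag, params.F0)
    f = np.where(arr > params.r_max, 0.0, f)
    return float(f) if np.ndim(r) == 0 else f


def _pairwise_displacements(positions: np.ndarray, domain_length: float):
    """All-pairs min-image displacements (N, N, 2) and distances (N, N)."""
    diff = positions[:, None, :] - positions[None, :, :]
    half = 0.5 * domain_length
    diff = np.mod(diff + half, domain_length) - half
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return diff, r

def _pairwise_forces(positions: np.ndarray, params: ModelParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Net pairwise force on every cell (N, 2); all-pairs sum.

    Coincident cells (r < 1e-9, possible straight after division) have no
    defined direction: each such pair receives a shared random unit
    vector with magnitude F0, applied equal-and-opposite so momentum is
    conserved.  ``rng`` is only consumed in that (measure-zero) case;
    kick angles are drawn in ascending (i, j) pair order.
    """
    n = len(positions)
    if n < 2:
        return np.zeros((n, 2))
    forces, coincident = _kernels.pairwise_forces(
        np.ascontiguousarray(positions, dtype=float),
        params.domain_length, params.epsilon, params.sigma,
        params.F0, params.r_max)
    for i, j in coincident:
        if rng is None:
            raise ValueError(
                "coincident cells require a random generator for the kick")
        theta = rng.uniform(0.0, 2.0 * np.pi)
        kick = params.F0 * np.array([np.cos(theta), np.sin(theta)])
        forces[i] += kick
        forces[j] -= kick
    return forces


def net_pairwise_force(i: int, population: CellPopulation,
                       params: ModelParams,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Net capped Lennard-Jones force on cell ``i`` (um/min)."""
    return _pairwise_forces(population.positions, params, rng)[i]


def random_motility_force(params: ModelParams,
                          rng: np.random.Generator) -> np.ndarray:
    """One Gaussian motility kick; per-component variance ``2D/dt``.

    The per-component choice yields the macroscopic two-dimensional
    mean-squared displacement ``4 D t``.
    """
    scale = math.sqrt(2.0 * params.D / params.dt)
    return rng.normal(0.0, scale, size=2)


# ---------------------------------------------------------------------------
# contact guidance
# ---------------------------------------------------------------------------

def guidance_weight(total_fraction, params: ModelParams):
    """Strength of contact guidance as a function of collagen density.

    ``Lambda(x) = (h(x) - h(0)) / (h(1) - h(0))`` with ``h(x) =
    (tanh(gamma (x - lambda_bar)) + 1) / 2``; a normalised sigmoid with
    ``Lambda(0) = 0`` and ``Lambda(1) = 1``, switching near the
    half-maximal area fraction ``lambda_bar``.
    """
    x = np.asarray(total_fraction, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite total area fraction")
    if np.any(x < -1e-9) or np.any(x > 1.0 + 1e-9):
        raise ValueError("total area fraction outside [0, 1]")
    x = np.clip(x, 0.0, 1.0)

    def h(v):
        return 0.5 * (np.tanh(params.gamma * (v - params.lambda_bar)) + 1.0)

    lam = (h(x) - h(0.0)) / (h(1.0) - h(0.0))
    return float(lam) if np.ndim(total_fraction) == 0 else lam


def apply_contact_guidance(omega_at_cell, total_fraction: float,
                           b, params: ModelParams) -> np.ndarray:
    """Reorient ``b`` by the guidance operator; the length is preserved.

    ``M = Lambda * Omega_hat + (1 - Lambda) * I`` is applied to ``b`` and
    the product rescaled back to ``|b|``, so guidance changes direction
    only.  A zero input maps to zero; the degenerate case ``M b = 0``
    with ``b != 0`` (fully aligned rank-1 tensor, ``b`` exactly
    perpendicular to the fibres) yields zero motion for that step.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite input vector")
    nb = float(np.hypot(b[0], b[1]))
    if nb == 0.0:
        return np.zeros(2)
    lam = guidance_weight(total_fraction, params)
    nxx, nxy, nyy = normalise_tensor(
        *omega_at_cell, mode=params.guidance_normalisation)
    mxx = lam * nxx + (1.0 - lam)
    myy = lam * nyy + (1.0 - lam)
    mxy = lam * nxy
    y = np.array([mxx * b[0] + mxy * b[1], mxy * b[0] + myy * b[1]])
    ny = float(np.hypot(y[0], y[1]))
    if ny < 1e-12 * nb:
        log.debug("degenerate guidance: M b = 0 for b = %s", b)
        return np.zeros(2)
    return y * (nb / ny)


def _apply_guidance_many(oxx, oxy, oyy, total_fraction, b,
                         params: ModelParams) -> np.ndarray:
    """Vectorised guidance application; b is (N, 2)."""
    lam = guidance_weight(total_fraction, params)
    nxx, nxy, nyy = normalise_tensor(
        oxx, oxy, oyy, mode=params.guidance_normalisation)
    one_minus = 1.0 - lam
    mxx = lam * nxx + one_minus
    myy = lam * nyy + one_minus
    mxy = lam * nxy
    yx = mxx * b[:, 0] + mxy * b[:, 1]
    yy = mxy * b[:, 0] + myy * b[:, 1]
    nb = np.hypot(b[:, 0], b[:, 1])
    ny = np.hypot(yx, yy)
    dead = ny < 1e-12 * nb
    scale = np.where(ny > 0.0, nb / np.where(ny > 0.0, ny, 1.0), 0.0)
    scale = np.where(dead, 0.0, scale)
    return np.column_stack([yx * scale, yy * scale])


# ---------------------------------------------------------------------------
# time stepping and proliferation
# ---------------------------------------------------------------------------

def euler_step_positions(population: CellPopulation, field: FibreField,
                         params: ModelParams,
                         rng: np.random.Generator) -> CellPopulation:
    """One forward-Euler position update for all cells, synchronously.

    Motility kicks and pairwise forces are evaluated from the state at
    ``t``; guidance is applied once to the combined vector; then ``X <-
    X + dt * M_hat [xi + sum F]`` for every cell at once.
    """
    n = population.n
    scale = math.sqrt(2.0 * params.D / params.dt)
    xi = rng.normal(0.0, scale, size=(n, 2))
    if params.epsilon > 0.0 and n > 1:
        forces = _pairwise_forces(population.positions, params, rng)
    else:
        forces = 0.0
    b = xi + forces
    oxx, oxy, oyy = field.sample(population.positions)
    tf = np.clip(oxx + oyy, 0.0, 1.0)
    v = _apply_guidance_many(oxx, oxy, oyy, tf, b, params)
    population.advance(population.unwrapped + params.dt * v)
    return population


def count_close_neighbours(i: int, population: CellPopulation,
                           params: ModelParams) -> int:
    """Number of cells within the repulsive range ``2^(1/6) sigma``.

    The boundary is inclusive; a 1e-9 um slack absorbs floating-point
    rounding of exact lattice spacings.
    """
    disp = min_image_displacement(population.positions,
                                  population.positions[i],
                                  population.domain_length)
    r = np.hypot(disp[:, 0], disp[:, 1])
    r[i] = np.inf
    return int(np.count_nonzero(r <= params.repulsion_range + 1e-9))


def _neighbour_counts(population: CellPopulation,
                      params: ModelParams) -> np.ndarray:
    """Close-neighbour counts for every cell at once."""
    if population.n < 2:
        return np.zeros(population.n, dtype=np.int64)
    return _kernels.neighbour_counts(
        np.ascontiguousarray(population.positions),
        population.domain_length, params.repulsion_range)


def division_probability(beta, params: ModelParams):
    """Per-step division probability ``(dt/Delta0)(1 - beta/6)``.

    Six is the maximum packing number: a cell with six or more close
    neighbours cannot divide.
    """
    beta_arr = np.asarray(beta, dtype=float)
    base = params.dt / params.Delta0
    p = np.where(beta_arr <= 6.0, base * (1.0 - beta_arr / 6.0), 0.0)
    p = np.clip(p, 0.0, None)
    return float(p) if np.ndim(beta) == 0 else p


def attempt_divisions(population: CellPopulation, params: ModelParams,
                      rng: np.random.Generator) -> CellPopulation:
    """One proliferation sweep over the cells present at its start.

    Each cell divides with the crowding-limited probability; daughters
    are placed ``sigma/2`` away at a uniform random angle, appended in
    ascending parent id, and cannot divide in their birth step.
    """
    if params.dt / params.Delta0 <= 0.0:
        return population
    n0 = population.n
    beta = _neighbour_counts(population, params)
    p = division_probability(beta, params)
    u = rng.random(n0)
    dividers = np.nonzero(u < p)[0]
    if len(dividers) == 0:
        return population
    angles = rng.uniform(0.0, 2.0 * np.pi, size=len(dividers))
    offset = 0.5 * params.sigma * np.column_stack(
        [np.cos(angles), np.sin(angles)])
    population.add_cells(population.unwrapped[dividers] + offset)
    return population
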