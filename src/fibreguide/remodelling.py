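"""Cell-driven evolution of the collagen fibre field.

Each cell remodels the fibre tensor within half a cell diameter of its
centre, weighted by a linear tent kernel.  Secretion deposits a rank-1
tensor aligned with the cell's time-averaged direction of motion,
throttled by the free area fraction ``1 - lambda1 - lambda2`` so a
saturated node receives nothing; degradation removes the existing tensor
at a first-order rate.  The update is forward Euler on the grid nodes,
with the pre-update trace used for the saturation factor.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .fibre_field import FibreField, _eigh2
from .mechanics import CellPopulation, ModelParams, VelocityMemory, \
    min_image_displacement

log = logging.getLogger(__name__)


class RemodellingStabilityError(RuntimeError):
    """Raised when the explicit degradation step would overshoot."""


def average_unit_velocity(i: int, memory: VelocityMemory):
    """Unit vector of cell ``i``'s average velocity, or ``None``.

    Computed from UNWRAPPED positions so periodic crossings cannot
    corrupt the direction.  Returns ``None`` for a newborn (zero-length
    window) or an effectively stationary cell (displacement below
    1e-9 um): such cells have no secretion direction.
    """
    if memory.window_min[i] <= 0.0:
        return None
    disp = memory.end[i] - memory.start[i]
    norm = float(np.hypot(disp[0], disp[1]))
    if norm < 1e-9:
        return None
    return disp / norm


def _unit_velocities(memory: VelocityMemory):
    """Vectorised averaged directions: (N, 2) units plus validity mask."""
    disp = memory.end - memory.start
    norm = np.hypot(disp[:, 0], disp[:, 1])
    valid = (memory.window_min > 0.0) & (norm >= 1e-9)
    safe = np.where(valid, norm, 1.0)
    return disp / safe[:, None], valid


def deposition_weight(cell_pos, node_pos, params: ModelParams) -> float:
    """Tent kernel ``1 - |dx|/(sigma/2)`` inside half a cell diameter."""
    disp = min_image_displacement(cell_pos, node_pos, params.domain_length)
    r = float(np.hypot(disp[..., 0], disp[..., 1]))
    radius = 0.5 * params.sigma
    return max(0.0, 1.0 - r / radius)


def remodel_field(field: FibreField, population: CellPopulation,
                  memory: VelocityMemory,
                  params: ModelParams) -> FibreField:
    """One forward-Euler secretion/degradation update of the field.

    Per node: ``Omega += dt * sum_i w_i [s (1 - trace) u_i u_i^T -
    d Omega]`` with the trace taken before the update.  Cells without a
    defined average direction still degrade but do not secrete.  After
    the update, tiny negative eigenvalues are clamped to zero and any
    trace overshooting 1 is rescaled back onto the constraint while
    preserving orientation.  Only nodes within ``sigma/2`` of some cell
    are touched.
    """
    if params.s == 0.0 and params.d == 0.0:
        return field
    n = population.n
    if n == 0:
        return field
    nx, ny = field.nx, field.ny
    radius = 0.5 * params.sigma

    units, valid = _unit_velocities(memory)
    size = nx * ny
    wsum = np.zeros(size)
    sxx = np.zeros(size)
    sxy = np.zeros(size)
    syy = np.zeros(size)
    maxw = _kernels.deposit_sums(
        np.ascontiguousarray(population.positions), units, valid,
        nx, ny, field.delta, radius, wsum, sxx, sxy, syy, params.s > 0.0)

    if params.d > 0.0 and params.d * params.dt * maxw >= 1.0:
        raise RemodellingStabilityError(
            f"degradation overshoots: d*dt*sum(w) = "
            f"{params.d * params.dt * maxw:.3g} >= 1 (d = {params.d}, "
            f"dt = {params.dt}, max kernel weight sum = {maxw:.3g})")

    touched = np.nonzero(wsum > 0.0)[0]
    if len(touched) == 0:
        return field
    oxx = field.oxx.ravel()
    oxy = field.oxy.ravel()
    oyy = field.oyy.ravel()
    tr_before = oxx[touched] + oyy[touched]
    sec = params.dt * params.s * (1.0 - tr_before)
    dec = params.dt * params.d * wsum[touched]
    new_xx = oxx[touched] + (sec * sxx[touched] - dec * oxx[touched])
    new_xy = oxy[touched] + (sec * sxy[touched] - dec * oxy[touched])
    new_yy = oyy[touched] + (sec * syy[touched] - dec * oyy[touched])

    # guard: clamp floating-point negative eigenvalues, rescale trace > 1
    l1, l2, vx, vy = _eigh2(new_xx, new_xy, new_yy)
    bad = l2 < 0.0
    if bad.any():
        l1c = np.maximum(l1[bad], 0.0)
        vxb, vyb = vx[bad], vy[bad]
        new_xx[bad] = l1c * vxb ** 2
        new_yy[bad] = l1c * vyb ** 2
        new_xy[bad] = l1c * vxb * vyb
    tr_after = new_xx + new_yy
    over = tr_after > 1.0
    if over.any():
        log.debug("trace overshoot at %d nodes; rescaling", over.sum())
        scale = 1.0 / tr_after[over]
        new_xx[over] *= scale
        new_xy[over] *= scale
        new_yy[over] *= scale

    oxx[touched] = new_xx
    oxy[touched] = new_xy
    oyy[touched] = new_yy
    return field
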