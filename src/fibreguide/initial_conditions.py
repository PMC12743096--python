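"""Reproducible initial conditions and named experiment presets.

The simulated experiments all start from a densely packed confluent disc
of cells at the domain centre, sitting on either an empty fibre bed or a
spatially uniform bed with a prescribed total area fraction, anisotropy
degree and major orientation.  Everything here is generated
programmatically and deterministically; presets bundle the printed
parameterisations of the published experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fibre_field import FibreField
from .mechanics import ModelParams


def packed_disc_cells(n: int, sigma: float, centre,
                      domain_length: float | None = None) -> np.ndarray:
    """Hexagonally packed confluent disc of ``n`` cell centres.

    Cells sit on a hexagonal lattice with the zero-force spacing
    ``2^(1/6) sigma``, filled outward from the centre ring by ring, so
    the initial cluster is confluent without a force transient.
    Deterministic: no randomness.
    """
    if n < 1:
        raise ValueError("need at least one cell")
    centre = np.asarray(centre, dtype=float)
    h = 2.0 ** (1.0 / 6.0) * sigma
    k = int(np.ceil(np.sqrt(n))) + 2
    i, j = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1),
                       indexing="ij")
    pts = np.column_stack([
        (i + 0.5 * j).ravel() * h,
        (j * np.sqrt(3.0) / 2.0).ravel() * h,
    ])
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    # ring-by-ring fill: order by quantised radius, then angle
    order = np.lexsort((ang, np.round(r / h * 1e6)))
    if len(order) < n:
        raise ValueError("internal lattice too small")  # pragma: no cover
    pts = pts[order[:n]] + centre
    if domain_length is not None:
        if np.any(pts < 0.0) or np.any(pts >= domain_length):
            raise ValueError(
                f"packed disc of {n} cells does not fit in the domain")
    return pts


def uniform_fibre_field(total_fraction: float, anisotropy: float,
                        major_angle_deg: float, nx: int, ny: int,
                        delta: float = 2.0) -> FibreField:
    """Spatially uniform fibre bed with prescribed density and alignment.

    Solves ``lambda1 + lambda2 = total`` and ``1 - lambda2/lambda1 = a``
    for the eigenvalues: ``lambda1 = total / (2 - a)``, ``lambda2 =
    lambda1 (1 - a)``, and orients the major eigenvector at
    ``major_angle_deg`` to the positive x-axis.
    """
    if not 0.0 <= total_fraction <= 1.0:
        raise ValueError("total area fraction must lie in [0, 1]")
    if not 0.0 <= anisotropy <= 1.0:
        raise ValueError("anisotropy degree must lie in [0, 1]")
    if total_fraction == 0.0:
        z = np.zeros((nx, ny))
        return FibreField(z, z.copy(), z.copy(), delta)
    l1 = total_fraction / (2.0 - anisotropy)
    l2 = l1 * (1.0 - anisotropy)
    th = np.radians(major_angle_deg)
    c, s = np.cos(th), np.sin(th)
    oxx = l1 * c * c + l2 * s * s
    oyy = l1 * s * s + l2 * c * c
    oxy = (l1 - l2) * c * s
    return FibreField(np.full((nx, ny), oxx), np.full((nx, ny), oxy),
                      np.full((nx, ny), oyy), delta)


@dataclass
class InitialCondition:
    """Cell positions plus a fibre-bed constructor."""

    n_cells: int = 100
    field_kind: str = "uniform"  # "uniform" | "empty"
    total_fraction: float = 0.0
    anisotropy: float = 0.0
    major_angle_deg: float = 90.0

    def build(self, params: ModelParams):
        """Realise ``(positions, FibreField)`` for the given parameters."""
        L = params.domain_length
        cells = packed_disc_cells(self.n_cells, params.sigma,
                                  (L / 2.0, L / 2.0), L)
        nx, ny = params.grid_shape
        if self.field_kind == "empty" or self.total_fraction == 0.0:
            field = uniform_fibre_field(0.0, 0.0, 0.0, nx, ny, params.delta)
        elif self.field_kind == "uniform":
            field = uniform_fibre_field(self.total_fraction, self.anisotropy,
                                        self.major_angle_deg, nx, ny,
                                        params.delta)
        else:
            raise ValueError(f"unknown field kind {self.field_kind!r}")
        return cells, field


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: named variants of the phenotype-showcase experiment: motility-dominated
#: versus interaction-dominated migration, and short- versus long-memory
#: secretion with different guidance sensitivities
FIG6_VARIANTS = {
    "low-motility-conserving": dict(D=0.075, epsilon=0.05, s=5.05e-6),
    "baseline-motility-conserving": dict(D=0.3, epsilon=0.05, s=5.05e-6),
    "secreting": dict(D=0.3, epsilon=0.05, s=0.05),
    "short-memory": dict(m=1.0, lambda_bar=0.005),
    "long-memory": dict(m=1200.0, lambda_bar=0.005),
    "long-memory-insensitive": dict(m=1200.0, lambda_bar=0.9),
}


def preset(name: str, variant: str | None = None, **overrides):
    """Named experiment configurations with the printed parameterisations.

    fig2 : de-novo secretion (large domain, empty bed, s = 0.025/min,
        d = 0.0025/min)
    fig3 : non-remodelling phenotype on a dense aligned bed (s = d = 0,
        total 0.8, a = 0.9, vertical major orientation)
    fig4a : degrading phenotype (s = 0) on a dense aligned bed (0.9/0.9)
    fig4b : secreting phenotype (d = 0) on a sparse aligned bed (0.1/0.9)
    fig5 : secretion/degradation sweep base (total 0.5, a = 0.9,
        vertical major orientation)
    fig6 : phenotype showcase on a near-empty isotropic bed (total 0.01,
        a = 0); pass ``variant`` to select a row (see ``FIG6_VARIANTS``)

    Keyword overrides are applied to the model parameters last.
    """
    from .engine import SimulationConfig  # local import avoids a cycle

    setup1 = dict(domain_length=540.0, T_final=5760.0)
    setup2 = dict(domain_length=360.0, T_final=3600.0)
    table = {
        "fig2": (dict(**setup1, s=0.025, d=0.0025),
                 InitialCondition(100, "empty")),
        "fig3": (dict(**setup2, s=0.0, d=0.0),
                 InitialCondition(100, "uniform", 0.8, 0.9, 90.0)),
        "fig4a": (dict(**setup2, s=0.0, d=2.0 ** -4),
                  InitialCondition(100, "uniform", 0.9, 0.9, 90.0)),
        "fig4b": (dict(**setup2, s=2.0 ** -4, d=0.0),
                  InitialCondition(100, "uniform", 0.1, 0.9, 90.0)),
        "fig5": (dict(**setup2, s=2.0 ** -4, d=2.0 ** -4),
                 InitialCondition(100, "uniform", 0.5, 0.9, 90.0)),
        "fig6": (dict(**setup2, s=0.05, d=0.0005),
                 InitialCondition(100, "uniform", 0.01, 0.0, 0.0)),
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; "
                         f"known: {sorted(table)}")
    kwargs, ic = table[name]
    if variant is not None:
        if name != "fig6":
            raise ValueError("variants exist only for the fig6 preset")
        if variant not in FIG6_VARIANTS:
            raise ValueError(f"unknown fig6 variant {variant!r}")
        kwargs.update(FIG6_VARIANTS[variant])
    kwargs.update(overrides)
    return SimulationConfig(params=ModelParams(**kwargs), initial=ic)
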