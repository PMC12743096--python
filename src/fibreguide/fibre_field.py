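"""Collagen orientation tensor fields.

The extracellular collagen bed is summarised, at every point of a periodic
rectangular grid, by a symmetric positive-semi-definite 2x2 orientation
tensor ``Omega``.  Its eigenvectors give the major and minor fibre
orientations (bidirectional: ``v`` and ``-v`` are the same fibre direction)
and its eigenvalues ``lambda1 >= lambda2 >= 0`` are the area fractions of
collagen aligned with them.  The trace ``lambda1 + lambda2`` is the total
collagen area fraction and is bounded by 1; the anisotropy degree
``a = 1 - lambda2/lambda1`` ranges from 0 (isotropic fibre bed) to 1
(perfectly aligned fibres).

This module provides the grid container plus the closed-form 2x2
eigendecomposition, anisotropy, normalisation and periodic bilinear
sampling primitives used by the contact-guidance machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: absolute tolerance for positive-semi-definiteness and trace checks
PSD_TOL = 1e-9


@dataclass
class EigenState:
    """Diagonalised form of a 2x2 orientation tensor.

    ``lambda1 >= lambda2 >= 0`` are area fractions; ``v1``/``v2`` are the
    orthonormal major/minor orientations, reported with the major angle
    in ``[0, pi)`` (fibres are bidirectional).
    """

    lambda1: float
    lambda2: float
    v1: np.ndarray
    v2: np.ndarray

    @property
    def angle1_rad(self) -> float:
        """Angle of the major orientation in ``[0, pi)``."""
        a = float(np.arctan2(self.v1[1], self.v1[0]))
        return a % np.pi

    def reconstruct(self) -> tuple[float, float, float]:
        """Return the tensor components ``(oxx, oxy, oyy)``."""
        v1, v2 = self.v1, self.v2
        oxx = self.lambda1 * v1[0] ** 2 + self.lambda2 * v2[0] ** 2
        oyy = self.lambda1 * v1[1] ** 2 + self.lambda2 * v2[1] ** 2
        oxy = self.lambda1 * v1[0] * v1[1] + self.lambda2 * v2[0] * v2[1]
        return float(oxx), float(oxy), float(oyy)


def _eigh2(oxx, oxy, oyy):
    """Vectorised closed-form eigensystem of symmetric 2x2 tensors.

    Returns ``(l1, l2, v1x, v1y)`` with ``l1 >= l2`` and the major
    eigenvector normalised into the upper half-plane (angle in [0, pi)).
    For (numerically) isotropic tensors the major direction is the
    tie-break ``(1, 0)``.
    """
    oxx = np.asarray(oxx, dtype=float)
    oxy = np.asarray(oxy, dtype=float)
    oyy = np.asarray(oyy, dtype=float)
    tr = oxx + oyy
    df = oxx - oyy
    disc = np.hypot(df, 2.0 * oxy)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    # Eigenvector of l1; branch chosen to avoid catastrophic cancellation.
    vx = np.where(df >= 0.0, 0.5 * (df + disc), oxy)
    vy = np.where(df >= 0.0, oxy, 0.5 * (disc - df))
    norm = np.hypot(vx, vy)
    degenerate = norm <= 1e-15 * np.maximum(1.0, np.abs(tr))
    safe = np.where(degenerate, 1.0, norm)
    vx = np.where(degenerate, 1.0, vx / safe)
    vy = np.where(degenerate, 0.0, vy / safe)
    # bidirectional convention: angle in [0, pi)
    flip = (vy < 0.0) | ((vy == 0.0) & (vx < 0.0))
    vx = np.where(flip, -vx, vx)
    vy = np.where(flip, -vy, vy)
    return l1, l2, vx, vy


def eigendecompose_2x2(oxx: float, oxy: float, oyy: float,
                       tol: float = PSD_TOL) -> EigenState:
    """Closed-form eigendecomposition of a symmetric PSD 2x2 tensor.

    Eigenvalues within ``tol`` below zero are clamped to 0; violations
    beyond ``tol`` (or non-finite input) are rejected.
    """
    comps = (oxx, oxy, oyy)
    if not all(np.isfinite(c) for c in comps):
        raise ValueError(f"non-finite tensor components {comps}")
    l1, l2, vx, vy = _eigh2(*comps)
    l1, l2 = float(l1), float(l2)
    if l2 < -tol:
        raise ValueError(
            f"tensor ({oxx}, {oxy}, {oyy}) is not positive semi-definite: "
            f"smallest eigenvalue {l2} < -{tol}")
    l1 = max(l1, 0.0)
    l2 = min(max(l2, 0.0), l1)
    v1 = np.array([float(vx), float(vy)])
    v2 = np.array([-v1[1], v1[0]])
    return EigenState(l1, l2, v1, v2)


def anisotropy_degree(lambda1: float, lambda2: float) -> float:
    """Anisotropy degree ``a = 1 - lambda2/lambda1`` in [0, 1].

    0 marks a perfectly isotropic fibre distribution, 1 perfect alignment.
    An empty tensor (``lambda1 = 0``) carries no directional information
    and is defined to have ``a = 0``.
    """
    if not (np.isfinite(lambda1) and np.isfinite(lambda2)):
        raise ValueError("non-finite eigenvalues")
    if lambda2 < 0.0:
        raise ValueError(f"negative area fraction lambda2 = {lambda2}")
    if lambda2 > lambda1:
        raise ValueError(f"lambda2 = {lambda2} exceeds lambda1 = {lambda1}")
    if lambda1 == 0.0:
        return 0.0
    return 1.0 - lambda2 / lambda1


def _anisotropy_many(l1, l2):
    """Vectorised anisotropy degree with the empty-tensor convention."""
    l1 = np.asarray(l1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 - l2 / l1
    return np.where(l1 > 0.0, a, 0.0)


def normalise_tensor(oxx, oxy, oyy, mode: str = "spectral"):
    """Normalised tensor ``Omega_hat`` used by the guidance operator.

    ``mode="spectral"`` (default): rescale so the largest eigenvalue is 1
    while preserving the eigenvalue ratio, ``Omega_hat = v1 v1^T +
    (lambda2/lambda1) v2 v2^T``; an empty tensor maps to the identity (no
    directional cue).  ``mode="trace"``: the alternative ``Omega / trace``
    normalisation (empty tensor again maps to the identity).  Both choices
    leave the direction of the guided motion unchanged in the isotropic
    limit; the spectral form additionally reduces to the identity there.

    Accepts scalars or equal-shaped arrays; returns ``(nxx, nxy, nyy)``.
    """
    oxx = np.asarray(oxx, dtype=float)
    oxy = np.asarray(oxy, dtype=float)
    oyy = np.asarray(oyy, dtype=float)
    if not (np.all(np.isfinite(oxx)) and np.all(np.isfinite(oxy))
            and np.all(np.isfinite(oyy))):
        raise ValueError("non-finite tensor components")
    scalar = oxx.ndim == 0
    if mode == "spectral":
        l1, l2, vx, vy = _eigh2(oxx, oxy, oyy)
        empty = l1 <= PSD_TOL
        safe_l1 = np.where(empty, 1.0, l1)
        ratio = np.clip(l2 / safe_l1, 0.0, 1.0)
        nxx = vx ** 2 + ratio * vy ** 2
        nyy = vy ** 2 + ratio * vx ** 2
        nxy = (1.0 - ratio) * vx * vy
        nxx = np.where(empty, 1.0, nxx)
        nyy = np.where(empty, 1.0, nyy)
        nxy = np.where(empty, 0.0, nxy)
    elif mode == "trace":
        tr = oxx + oyy
        empty = tr <= PSD_TOL
        safe = np.where(empty, 1.0, tr)
        nxx = np.where(empty, 1.0, oxx / safe)
        nxy = np.where(empty, 0.0, oxy / safe)
        nyy = np.where(empty, 1.0, oyy / safe)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if scalar:
        return float(nxx), float(nxy), float(nyy)
    return nxx, nxy, nyy


def spectral_normalise(oxx, oxy, oyy):
    """``normalise_tensor`` with the default spectral convention."""
    return normalise_tensor(oxx, oxy, oyy, mode="spectral")


@dataclass
class FibreField:
    """Periodic grid of collagen orientation tensors.

    Tensor components live on the nodes of a uniform grid with spacing
    ``delta`` (default 2 um); node ``(i, j)`` sits at ``(i*delta,
    j*delta)`` and the domain tiles periodically, so ``nx*delta`` by
    ``ny*delta`` is the physical domain.
    """

    oxx: np.ndarray
    oxy: np.ndarray
    oyy: np.ndarray
    delta: float = 2.0

    def __post_init__(self):
        self.oxx = np.ascontiguousarray(self.oxx, dtype=float)
        self.oxy = np.ascontiguousarray(self.oxy, dtype=float)
        self.oyy = np.ascontiguousarray(self.oyy, dtype=float)
        if not (self.oxx.shape == self.oxy.shape == self.oyy.shape):
            raise ValueError("component grids must share a shape")
        if self.oxx.ndim != 2:
            raise ValueError("component grids must be 2-D")
        if self.delta <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def nx(self) -> int:
        return self.oxx.shape[0]

    @property
    def ny(self) -> int:
        return self.oxx.shape[1]

    @property
    def domain_length_x(self) -> float:
        return self.nx * self.delta

    @property
    def domain_length_y(self) -> float:
        return self.ny * self.delta

    def trace(self) -> np.ndarray:
        return self.oxx + self.oyy

    def eigensystem(self):
        """Per-node ``(lambda1, lambda2, v1x, v1y)`` arrays."""
        return _eigh2(self.oxx, self.oxy, self.oyy)

    def anisotropy(self) -> np.ndarray:
        l1, l2, _, _ = self.eigensystem()
        return _anisotropy_many(np.maximum(l1, 0.0), np.clip(l2, 0.0, None))

    def node_coordinates(self):
        """Meshgrid ``(x, y)`` of node positions in um (indexing='ij')."""
        x = np.arange(self.nx) * self.delta
        y = np.arange(self.ny) * self.delta
        return np.meshgrid(x, y, indexing="ij")

    def copy(self) -> "FibreField":
        return FibreField(self.oxx.copy(), self.oxy.copy(),
                          self.oyy.copy(), self.delta)

    def validate(self, tol: float = PSD_TOL) -> None:
        """Assert the PSD and trace invariants at every node."""
        for name, comp in (("oxx", self.oxx), ("oyy", self.oyy)):
            if np.any(comp < -tol):
                raise ValueError(f"{name} below -{tol} somewhere")
        det = self.oxx * self.oyy - self.oxy ** 2
        if np.any(det < -tol):
            raise ValueError("determinant below tolerance: not PSD")
        tr = self.trace()
        if np.any(tr < -tol) or np.any(tr > 1.0 + tol):
            raise ValueError("total area fraction outside [0, 1]")

    # -- sampling -----------------------------------------------------

    def sample(self, point):
        """Periodic bilinear interpolation of the tensor at ``point``.

        ``point`` may be a single 2-vector or an ``(N, 2)`` array of
        positions (um), anywhere in the plane; positions wrap into the
        domain.  Each component is interpolated independently over the
        four surrounding nodes, so the result stays symmetric and its
        trace is bounded by the corner traces.
        """
        p = np.asarray(point, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite sample point")
        scalar = p.ndim == 1
        p = np.atleast_2d(p)
        gx = np.mod(p[:, 0], self.domain_length_x) / self.delta
        gy = np.mod(p[:, 1], self.domain_length_y) / self.delta
        i0 = np.floor(gx).astype(np.intp) % self.nx
        j0 = np.floor(gy).astype(np.intp) % self.ny
        fx = gx - np.floor(gx)
        fy = gy - np.floor(gy)
        i1 = (i0 + 1) % self.nx
        j1 = (j0 + 1) % self.ny
        w00 = (1.0 - fx) * (1.0 - fy)
        w10 = fx * (1.0 - fy)
        w01 = (1.0 - fx) * fy
        w11 = fx * fy

        def interp(c):
            return (w00 * c[i0, j0] + w10 * c[i1, j0]
                    + w01 * c[i0, j1] + w11 * c[i1, j1])

        oxx = interp(self.oxx)
        oxy = interp(self.oxy)
        oyy = interp(self.oyy)
        if scalar:
            return float(oxx[0]), float(oxy[0]), float(oyy[0])
        return oxx, oxy, oyy

    # -- snapshots ----------------------------------------------------

    def to_hdf5(self, path, time_min: float = 0.0) -> None:
        """Write the field (plus derived eigen-quantities) to HDF5.

        Timestamps are disabled on every dataset so identical fields
        produce byte-identical files.
        """
        import h5py

        l1, l2, vx, vy = self.eigensystem()
        angle = np.degrees(np.mod(np.arctan2(vy, vx), np.pi))
        with h5py.File(path, "w") as f:
            for name, data in (("oxx", self.oxx), ("oxy", self.oxy),
                               ("oyy", self.oyy), ("lambda1", l1),
                               ("lambda2", l2), ("angle1_deg", angle)):
                f.create_dataset(name, data=data, track_times=False)
            f.attrs["delta"] = float(self.delta)
            f.attrs["time_min"] = float(time_min)

    @classmethod
    def from_hdf5(cls, path) -> "FibreField":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["oxx"][...], f["oxy"][...], f["oyy"][...],
                       delta=float(f.attrs["delta"]))


def sample_field(field: FibreField, point):
    """Module-level alias for :meth:`FibreField.sample`."""
    return field.sample(point)
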