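"""Invasion signatures: density profiles, Jensen-Shannon distance,
radial anisotropy, region angle statistics, MSD, and the
secretion/degradation sweep.

The headline sweep measures how far the horizontal invasion profile of a
secreting-and-degrading phenotype departs from the matched non-degrading
phenotype (same secretion rate, same random seeds), using the
Jensen-Shannon distance between the y-averaged x-density histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .fibre_field import FibreField

#: nodes with total area fraction below this are treated as devoid of
#: collagen: orientation and anisotropy are undefined there
TRACE_FLOOR = 0.01


@dataclass
class DensityProfile:
    """Cell counts per x-bin (y-averaged by projection onto x)."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def density_profile_x(cells, bin_width: float,
                      domain_length: float) -> DensityProfile:
    """Histogram of cell x-coordinates over uniform bins spanning [0, L).

    ``cells`` may be an (N, 2) position array, a 1-D array of
    x-coordinates, or a snapshot DataFrame with an ``x_um`` column.  If
    the bin width does not divide the domain it is adjusted to the
    nearest divisor with a warning.
    """
    if isinstance(cells, pd.DataFrame):
        x = cells["x_um"].to_numpy()
    else:
        arr = np.asarray(cells, dtype=float)
        x = arr[:, 0] if arr.ndim == 2 else arr
    nbins = max(1, int(round(domain_length / bin_width)))
    if abs(nbins * bin_width - domain_length) > 1e-9:
        warnings.warn(
            f"bin width {bin_width} does not divide the domain; "
            f"using {domain_length / nbins:.6g} um", stacklevel=2)
    counts, edges = np.histogram(np.mod(x, domain_length),
                                 bins=nbins, range=(0.0, domain_length))
    return DensityProfile(edges=edges, counts=counts.astype(float))


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance between two histograms, base-2 logs.

    Inputs are normalised to probability vectors; the distance is the
    square root of the symmetrised KL-based divergence and lies in
    [0, 1]: 0 for identical distributions, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share a binning")
    if np.any(p < 0.0) or np.any(q < 0.0):
        raise ValueError("histogram entries must be non-negative")
    if p.sum() <= 0.0 or q.sum() <= 0.0:
        raise ValueError("each histogram needs at least one positive entry")
    return float(np.clip(jensenshannon(p, q, base=2), 0.0, 1.0))


def radial_anisotropy_profile(field: FibreField, centre=None,
                              ring_width: float = 4.0,
                              trace_floor: float = TRACE_FLOOR
                              ) -> pd.DataFrame:
    """Mean anisotropy degree in concentric rings about ``centre``.

    Nodes with trace below ``trace_floor`` are devoid of collagen and
    excluded; rings with no valid node report NaN.
    """
    if centre is None:
        centre = (field.domain_length_x / 2.0, field.domain_length_y / 2.0)
    x, y = field.node_coordinates()
    r = np.hypot(x - centre[0], y - centre[1])
    a = field.anisotropy()
    valid = field.trace() >= trace_floor
    rmax = r.max()
    nrings = int(np.ceil(rmax / ring_width)) or 1
    ring = np.minimum((r / ring_width).astype(int), nrings - 1)
    rows = []
    for k in range(nrings):
        sel = (ring == k) & valid
        rows.append({
            "r_inner_um": k * ring_width,
            "r_outer_um": (k + 1) * ring_width,
            "mean_anisotropy": float(a[sel].mean()) if sel.any() else np.nan,
            "n_nodes": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def region_masks(field: FibreField, centre=None):
    """Quadrant-sector masks L/R/T/B bounded by the domain diagonals.

    Ties on the diagonals go to the horizontal (L/R) sectors.
    """
    if centre is None:
        centre = (field.domain_length_x / 2.0, field.domain_length_y / 2.0)
    x, y = field.node_coordinates()
    dx = x - centre[0]
    dy = y - centre[1]
    horiz = np.abs(dx) >= np.abs(dy)
    return {
        "L": horiz & (dx < 0), "R": horiz & (dx >= 0),
        "T": ~horiz & (dy > 0), "B": ~horiz & (dy < 0),
    }


def region_angle_distribution(field: FibreField, centre=None,
                              trace_floor: float = TRACE_FLOOR) -> dict:
    """Major-orientation angles (deg, in [0, 180)) per L/R/T/B region.

    Only nodes carrying collagen (trace >= ``trace_floor``) contribute.
    """
    _, _, vx, vy = field.eigensystem()
    angles = np.degrees(np.mod(np.arctan2(vy, vx), np.pi))
    valid = field.trace() >= trace_floor
    masks = region_masks(field, centre)
    return {name: angles[mask & valid] for name, mask in masks.items()}


def region_angle_summary(field: FibreField, centre=None,
                         trace_floor: float = TRACE_FLOOR) -> pd.DataFrame:
    """Quartile summary of the per-region angle distributions."""
    rows = []
    for name, ang in region_angle_distribution(field, centre,
                                               trace_floor).items():
        if len(ang) == 0:
            rows.append({"region": name, "n_nodes": 0, "q1_deg": np.nan,
                         "median_deg": np.nan, "q3_deg": np.nan})
        else:
            q1, med, q3 = np.percentile(ang, [25, 50, 75])
            rows.append({"region": name, "n_nodes": len(ang),
                         "q1_deg": q1, "median_deg": med, "q3_deg": q3})
    return pd.DataFrame(rows)


def msd(unwrapped_history: np.ndarray, cells=None) -> np.ndarray:
    """Ensemble mean-squared displacement from an unwrapped history.

    ``unwrapped_history`` is a (T, N, 2) array of unwrapped positions;
    ``cells`` optionally restricts the ensemble to a subset of columns.
    Returns the (T,) curve ``<|X(t) - X(0)|^2>``.
    """
    traj = np.asarray(unwrapped_history, dtype=float)
    if cells is not None:
        traj = traj[:, cells]
    disp = traj - traj[0]
    return np.einsum("tnk,tnk->tn", disp, disp).mean(axis=1)


# ---------------------------------------------------------------------------
# secretion/degradation sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Outcome of the secretion/degradation sweep.

    ``table``: mean JSD indexed by degradation rate (rows) and secretion
    rate (columns).  ``critical_s``: the smallest tested secretion rate
    at which the invasion profile stays within the JSD threshold of the
    matched non-degrading phenotype for every tested degradation rate
    (None if no tested rate qualifies).
    """

    table: pd.DataFrame
    critical_s: float | None
    threshold: float


def critical_secretion_sweep(base_config=None, s_values=None, d_values=None,
                             reps: int = 3, t_eval_min: float = 2520.0,
                             threshold: float = 0.2,
                             bin_width_um: float = 12.0,
                             matched_seeds: bool = True,
                             base_seed: int = 0,
                             progress=None) -> SweepResult:
    """JSD(s, d) heat map against the matched d = 0 phenotype.

    For each secretion rate ``s`` and repetition, a reference run with
    ``d = 0`` shares the seed of the (s, d) runs (``matched_seeds``), so
    the distance isolates the effect of degradation rather than
    realisation noise.  Each heat-map cell is the mean over ``reps`` of
    the Jensen-Shannon distance between the y-averaged x-density
    profiles at ``t_eval_min``.
    """
    from .engine import Simulation
    from .initial_conditions import preset

    if base_config is None:
        base_config = preset("fig5")
    if s_values is None:
        s_values = [2.0 ** -k for k in range(10, 3, -1)]
    if d_values is None:
        d_values = [2.0 ** -10, 2.0 ** -7, 2.0 ** -4]
    s_values = sorted(float(v) for v in s_values)
    d_values = sorted(float(v) for v in d_values)
    L = base_config.params.domain_length

    def profile_at(s, d, seed):
        cfg = base_config.with_params(s=s, d=d, seed=seed)
        sim = Simulation(cfg)
        sim.run_until(t_eval_min)
        return density_profile_x(sim.population.positions,
                                 bin_width_um, L).counts

    jsd = np.zeros((len(d_values), len(s_values)))
    for rep in range(reps):
        for si, s in enumerate(s_values):
            seed_ref = (base_seed * 1009 + rep) % (2 ** 31)
            ref = profile_at(s, 0.0, seed_ref)
            for di, d in enumerate(d_values):
                seed_run = seed_ref if matched_seeds else \
                    (seed_ref + 7919 * (di + 1)) % (2 ** 31)
                prof = profile_at(s, d, seed_run)
                jsd[di, si] += jensen_shannon_distance(prof, ref)
                if progress is not None:
                    progress(rep, s, d)
    jsd /= reps
    table = pd.DataFrame(jsd, index=pd.Index(d_values, name="d_per_min"),
                         columns=pd.Index(s_values, name="s_per_min"))
    critical = None
    for si, s in enumerate(s_values):
        if np.all(jsd[:, si] < threshold):
            critical = s
            break
    return SweepResult(table=table, critical_s=critical, threshold=threshold)
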