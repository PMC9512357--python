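"""Evaluation of computed dose: output factors, gamma analysis, profiles.

Output factors follow the small-field protocol: dose at the field center at
100 mm depth in the water phantom, relative to the dose of the 100 mm x
100 mm reference field of the same beam quality at the same depth.  Point
doses are read as the average of the 3x3x3 voxel neighborhood to suppress
Monte Carlo noise; the same readout is applied to the test and the
reference grids so it cancels in the ratio.

The gamma index is the standard one-directional (reference vs. evaluated)
global gamma: for each reference voxel above the low-dose threshold,

    gamma(r) = min over the search neighborhood of
               sqrt( (D_eval(r+s) - D_ref(r))^2 / dD^2 + |s|^2 / dta^2 ),

with dD an absolute criterion derived from a percentage of the
normalization dose.  The evaluated grid is sampled with trilinear
sub-voxel interpolation on a 0.2 mm search step out to 3x the
distance-to-agreement.  A voxel passes when gamma < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .transport import DoseGrid

__all__ = [
    "OutputFactorResult",
    "GammaResult",
    "output_factor",
    "gamma_pass_rate",
    "extract_profile",
    "dvh",
]

GAMMA_SEARCH_STEP_MM = 0.2
GAMMA_SEARCH_FACTOR = 3.0


@dataclass(frozen=True)
class OutputFactorResult:
    field_width_mm: float
    offset_mm: tuple[float, float]
    quality: str
    dose_cgy: float
    reference_dose_cgy: float
    factor: float
    uncertainty: float  # relative, both runs in quadrature


@dataclass
class GammaResult:
    dose_criterion_cgy: float
    dta_mm: float
    threshold_fraction: float
    pass_fraction_pct: float
    gamma: np.ndarray  # per-voxel gamma, NaN below the threshold
    n_evaluated: int


def output_factor(
    test_dose: DoseGrid,
    ref_dose: DoseGrid,
    point_mm,
    field_width_mm: float = 0.0,
    offset_mm: tuple[float, float] = (0.0, 0.0),
    quality: str = "",
    ref_point_mm=None,
    neighborhood: int = 1,
) -> OutputFactorResult:
    """Dose ratio test/reference at a measurement point.

    ``point_mm`` is the test-field readout point (the offset field center at
    measurement depth); the reference field is read at ``ref_point_mm``
    (default: beam axis at the same depth).  Both grids must share geometry.
    """
    if test_dose.values.shape != ref_dose.values.shape or not np.allclose(
        test_dose.origin_mm, ref_dose.origin_mm
    ):
        raise ValueError("test and reference dose grids must share geometry")
    if ref_point_mm is None:
        ref_point_mm = (0.0, 0.0, point_mm[2])
    d_test = test_dose.point_dose(point_mm, neighborhood=neighborhood)
    d_ref = ref_dose.point_dose(ref_point_mm, neighborhood=neighborhood)
    if d_ref <= 0:
        raise ValueError("reference dose is zero at the measurement point")
    unc = 0.0
    for grid, pt in ((test_dose, point_mm), (ref_dose, ref_point_mm)):
        if grid.uncertainty is not None:
            i, j, k = grid._index_of(pt)
            r = neighborhood
            sl = tuple(
                slice(max(0, c - r), min(n, c + r + 1))
                for c, n in zip((i, j, k), grid.values.shape)
            )
            u = grid.uncertainty[sl]
            u = u[np.isfinite(u)]
            if u.size:
                # neighborhood-mean uncertainty; voxel noise is partially
                # independent, so this is a conservative (upper) estimate
                unc += float(np.mean(u)) ** 2 / u.size
    return OutputFactorResult(
        field_width_mm=field_width_mm,
        offset_mm=tuple(offset_mm),
        quality=quality,
        dose_cgy=d_test,
        reference_dose_cgy=d_ref,
        factor=d_test / d_ref,
        uncertainty=math.sqrt(unc),
    )


# ---------------------------------------------------------------------------
# Gamma analysis

@njit(cache=True)
def _trilinear(ev, fx, fy, fz):
    nx, ny, nz = ev.shape
    i = int(math.floor(fx))
    j = int(math.floor(fy))
    k = int(math.floor(fz))
    i = min(max(i, 0), nx - 2 if nx > 1 else 0)
    j = min(max(j, 0), ny - 2 if ny > 1 else 0)
    k = min(max(k, 0), nz - 2 if nz > 1 else 0)
    tx = fx - i
    ty = fy - j
    tz = fz - k
    i1 = i + 1 if nx > 1 else i
    j1 = j + 1 if ny > 1 else j
    k1 = k + 1 if nz > 1 else k
    c00 = ev[i, j, k] * (1 - tx) + ev[i1, j, k] * tx
    c10 = ev[i, j1, k] * (1 - tx) + ev[i1, j1, k] * tx
    c01 = ev[i, j, k1] * (1 - tx) + ev[i1, j, k1] * tx
    c11 = ev[i, j1, k1] * (1 - tx) + ev[i1, j1, k1] * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


@njit(cache=True)
def _gamma_kernel(ref, ev, dv, dd_abs, dta, thresh, offsets, off_r2, gamma_out):
    nx, ny, nz = ref.shape
    dta2 = dta * dta
    n_off = offsets.shape[0]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                d_r = ref[i, j, k]
                if d_r < thresh:
                    gamma_out[i, j, k] = np.nan
                    continue
                best = 1.0e30
                for t in range(n_off):
                    dist_term = off_r2[t] / dta2
                    if dist_term >= best:
                        break  # offsets sorted by distance: no improvement possible
                    fx = i + offsets[t, 0] / dv
                    fy = j + offsets[t, 1] / dv
                    fz = k + offsets[t, 2] / dv
                    if fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1 \
                            or fz < 0.0 or fz > nz - 1:
                        continue
                    d_e = _trilinear(ev, fx, fy, fz)
                    dd = (d_e - d_r) / dd_abs
                    g = dd * dd + dist_term
                    if g < best:
                        best = g
                gamma_out[i, j, k] = math.sqrt(best)


def _search_offsets(dta_mm: float, step_mm: float, dims: tuple[bool, bool, bool]):
    """Displacements (mm) on the search lattice, sorted by distance."""
    radius = GAMMA_SEARCH_FACTOR * dta_mm
    n = int(math.floor(radius / step_mm))
    ax = [np.arange(-n, n + 1) * step_mm if d else np.zeros(1) for d in dims]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r2 = np.einsum("ij,ij->i", offs, offs)
    keep = r2 <= radius**2 + 1e-12
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return np.ascontiguousarray(offs[order]), np.ascontiguousarray(r2[order])


def gamma_pass_rate(
    eval_dose: DoseGrid,
    ref_dose: DoseGrid,
    dose_crit_pct: float = 2.0,
    norm_dose: float = 100.0,
    dta_mm: float = 2.0,
    threshold_pct: float = 10.0,
    search_step_mm: float = GAMMA_SEARCH_STEP_MM,
) -> GammaResult:
    """Global gamma pass rate of ``eval_dose`` against ``ref_dose``.

    The dose criterion is ``dose_crit_pct`` percent of ``norm_dose``
    (absolute, "global" normalization); only reference voxels above
    ``threshold_pct`` percent of the reference maximum are evaluated.  The
    comparison is one-directional (reference voxels against the
    interpolated evaluated grid).
    """
    if eval_dose.values.shape != ref_dose.values.shape or not np.allclose(
        eval_dose.origin_mm, ref_dose.origin_mm
    ):
        raise ValueError("gamma analysis requires co-registered grids")
    if dose_crit_pct <= 0 or dta_mm <= 0 or norm_dose <= 0:
        raise ValueError("gamma criteria must be positive")
    ref = np.ascontiguousarray(ref_dose.values, dtype=np.float64)
    ev = np.ascontiguousarray(eval_dose.values, dtype=np.float64)
    dd_abs = dose_crit_pct / 100.0 * norm_dose
    thresh = threshold_pct / 100.0 * ref.max()
    dims = tuple(s > 1 for s in ref.shape)
    offsets, off_r2 = _search_offsets(dta_mm, search_step_mm, dims)
    gamma = np.empty_like(ref)
    _gamma_kernel(ref, ev, ref_dose.voxel_size_mm, dd_abs, dta_mm, thresh,
                  offsets, off_r2, gamma)
    evaluated = np.isfinite(gamma)
    n_eval = int(evaluated.sum())
    passed = int((gamma[evaluated] < 1.0).sum()) if n_eval else 0
    return GammaResult(
        dose_criterion_cgy=dd_abs,
        dta_mm=dta_mm,
        threshold_fraction=threshold_pct / 100.0,
        pass_fraction_pct=100.0 * passed / n_eval if n_eval else float("nan"),
        gamma=gamma,
        n_evaluated=n_eval,
    )


# ---------------------------------------------------------------------------
# Profiles / DVH

_AXES = {"x": 0, "y": 1, "z": 2, "depth": 2}


def extract_profile(dose: DoseGrid, axis: str, position_mm) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-voxel line profile along ``axis`` through ``position_mm``.

    ``position_mm`` gives the coordinates of the two fixed axes (in axis
    order, the moving axis skipped) or a full 3-vector.  Returns
    (voxel-center positions, dose values).
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    a = _AXES[axis]
    pos = list(position_mm)
    if len(pos) == 2:
        pos.insert(a, dose.origin_mm[a] + dose.voxel_size_mm / 2)
    idx = list(dose._index_of(pos))
    sl = [idx[0], idx[1], idx[2]]
    sl[a] = slice(None)
    values = dose.values[tuple(sl)]
    centers = dose.origin_mm[a] + dose.voxel_size_mm * (np.arange(dose.values.shape[a]) + 0.5)
    return centers, np.asarray(values)


def dvh(dose: DoseGrid, mask: np.ndarray, n_bins: int = 200):
    """Cumulative dose-volume histogram of the voxels selected by ``mask``.

    Convenience for synthetic labeled masks; returns (dose_edges,
    volume_fraction >= dose).
    """
    vals = dose.values[mask.astype(bool)]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    edges = np.linspace(0.0, float(vals.max()) * 1.001, n_bins)
    frac = np.array([(vals >= e).mean() for e in edges])
    return edges, frac
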