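"""Automated MEG-MRI co-registration and the co-registration error metric.

The automated pipeline mirrors the standard landmark + ICP procedure:

1. estimate the subject's MRI-frame fiducials by mapping template (MNI305
   average) fiducial coordinates through the template-to-subject affine;
2. fit an initial rigid transform using only the three landmarks;
3. refine with an initial run of iterative closest points (ICP) against
   the scalp surface;
4. drop outlier headshape points, i.e. those more than 5 mm from the
   surface under the current fit;
5. run ICP again on the retained points.

The co-registration error is the median distance from each digitized
headshape point to the nearest point on the MRI scalp surface under the
final transform.  Errors for an externally supplied (e.g. manual)
transform are computed the same way without any fitting.

Conventions: transforms map MRI -> head; to measure distances, the
*inverse* transform is applied to the headshape points, bringing them
into the MRI frame of the surface (equivalent to transforming the mesh,
and much cheaper).  Fiducial- and HPI-role points are excluded from both
ICP fitting and the error metric; the metric is computed over ALL
headshape-role points, including any dropped as outliers during fitting
(per-inlier summaries are reported as secondary fields).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .surface import HeadSurface, HeadshapePointSet, SurfaceDistanceQuery
from .transforms import (DegenerateGeometryError, RigidTransform,
                         TransformParams, decompose, fit_landmarks, invert,
                         recompose)

__all__ = [
    "CoregConfig",
    "CoregResult",
    "CoregistrationError",
    "template_fiducials_to_subject",
    "icp",
    "remove_outliers",
    "auto_coregister",
    "evaluate_transform",
    "MNI305_FIDUCIALS_MM",
]

#: Average fiducial coordinates on a template head (mm, template frame).
#: Stand-in values on the package's synthetic template; mapped through a
#: template-to-subject affine by :func:`template_fiducials_to_subject`.
MNI305_FIDUCIALS_MM = {
    "nasion": np.array([0.0, 84.0, -40.0]),
    "lpa": np.array([-75.0, 0.0, -44.0]),
    "rpa": np.array([75.0, 0.0, -44.0]),
}

SCHEMA_VERSION = 1


class CoregistrationError(RuntimeError):
    """Raised when the co-registration pipeline cannot proceed."""


@dataclass(frozen=True)
class CoregConfig:
    """Tunable pipeline parameters.

    The 5 mm outlier threshold and the 2 mm quality heuristic are the
    field-standard values.  Iteration counts are caps: each ICP stage
    stops early once the RMS distance improves by less than
    ``convergence_tol`` per iteration.  "Several" initial iterations is
    realized as a cap of 30; the final stage gets a generous cap of 200
    because point-to-point ICP approaches its optimum along slow
    tangential-sliding modes, and on low-noise data a tight cap leaves a
    measurable pose error (on noisy data the tolerance stops it long
    before the cap).
    """

    n_icp_initial: int = 30
    n_icp_final: int = 200
    convergence_tol: float = 1e-6  #: mm change in RMS distance
    outlier_threshold: float = 5.0  #: mm
    quality_threshold: float = 2.0  #: mm; error above this is flagged

    def __post_init__(self) -> None:
        if self.n_icp_initial < 1 or self.n_icp_final < 1:
            raise ValueError("iteration counts must be >= 1")
        if min(self.convergence_tol, self.outlier_threshold,
               self.quality_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CoregResult:
    """Outcome of a co-registration (fitted or merely evaluated).

    ``distances_all`` covers every headshape-role point under the final
    transform, in input order; ``median_error`` and the IQR bounds are its
    50th/25th/75th percentiles (linear interpolation).  ``outlier_indices``
    index into the headshape-role points removed at the outlier-rejection
    step; ``iteration_trace`` holds one mean-distance trace per ICP stage.
    """

    transform: RigidTransform
    distances_all: np.ndarray
    median_error: float
    iqr_low: float
    iqr_high: float
    outlier_indices: np.ndarray
    converged: bool
    iteration_trace: tuple
    quality_flag: bool
    landmark_rms: float = float("nan")
    median_error_inliers: float = float("nan")
    n_headshape_points: int = 0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "transform": [float(x) for x in self.transform.matrix.ravel()],
            "distances_all": [float(d) for d in self.distances_all],
            "median_error": float(self.median_error),
            "iqr_low": float(self.iqr_low),
            "iqr_high": float(self.iqr_high),
            "outlier_indices": [int(i) for i in self.outlier_indices],
            "converged": bool(self.converged),
            "iteration_trace": [list(map(float, tr))
                                for tr in self.iteration_trace],
            "quality_flag": bool(self.quality_flag),
            "landmark_rms": float(self.landmark_rms),
            "median_error_inliers": float(self.median_error_inliers),
            "n_headshape_points": int(self.n_headshape_points),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CoregResult":
        return cls(
            transform=RigidTransform(np.array(d["transform"]).reshape(4, 4)),
            distances_all=np.array(d["distances_all"], dtype=float),
            median_error=d["median_error"],
            iqr_low=d["iqr_low"],
            iqr_high=d["iqr_high"],
            outlier_indices=np.array(d["outlier_indices"], dtype=np.int64),
            converged=d["converged"],
            iteration_trace=tuple(tuple(t) for t in d["iteration_trace"]),
            quality_flag=d["quality_flag"],
            landmark_rms=d.get("landmark_rms", float("nan")),
            median_error_inliers=d.get("median_error_inliers", float("nan")),
            n_headshape_points=d.get("n_headshape_points", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CoregResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def template_fiducials_to_subject(template_fiducials: dict,
                                  template_to_subject: np.ndarray) -> dict:
    """Map labeled template fiducials through a template->subject affine.

    The affine may include scaling/shear (template registration is affine,
    not rigid); it must be invertible.
    """
    aff = np.asarray(template_to_subject, dtype=float)
    if aff.shape != (4, 4):
        raise ValueError(f"expected a 4x4 affine, got {aff.shape}")
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValueError("template-to-subject affine is singular")
    out = {}
    for name, pt in template_fiducials.items():
        h = aff @ np.append(np.asarray(pt, dtype=float), 1.0)
        out[name] = h[:3] / h[3]
    return out


def _summaries(distances: np.ndarray) -> tuple[float, float, float]:
    return (float(np.median(distances)),
            float(np.percentile(distances, 25)),
            float(np.percentile(distances, 75)))


def icp(points: np.ndarray, surface: HeadSurface | SurfaceDistanceQuery,
        init: RigidTransform, n_iter: int = 20,
        tol: float = 1e-6) -> tuple[RigidTransform, list[float]]:
    """Iterative closest points from head-frame points to an MRI surface.

    Alternates (a) corresponding each inverse-transformed point with its
    exact nearest point on the surface and (b) solving the rigid Procrustes
    problem to those correspondences, until the mean corresponded distance
    changes by less than ``tol`` mm or ``n_iter`` updates have been
    applied.  An update that would *increase* the mean distance (possible
    because the refit minimizes summed squared distance, not the mean) is
    rejected and iteration stops, so the returned trace is monotonically
    non-increasing.

    Returns the refined transform (MRI -> head) and the mean-distance
    trace, one entry per evaluated state including the final one.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("ICP needs at least 3 points")
    if np.allclose(pts, pts[0], atol=1e-12):
        raise DegenerateGeometryError("all ICP points coincident")
    query = (surface if isinstance(surface, SurfaceDistanceQuery)
             else SurfaceDistanceQuery(surface))

    def pose(t: RigidTransform) -> np.ndarray:
        p = decompose(t)
        return p.as_array()

    def unpose(vec: np.ndarray) -> RigidTransform:
        return recompose(TransformParams(*vec))

    def rms_dist(t: RigidTransform):
        d, m = query.query(invert(t).apply(pts))
        return float(np.sqrt(np.mean(d * d))), m

    transform = init
    rms_cur, matched = rms_dist(transform)
    trace = [rms_cur]
    delta_prev: np.ndarray | None = None
    for _ in range(n_iter):
        # refit head->MRI mapping onto current correspondences
        head_to_mri = fit_landmarks(pts, matched).transform
        candidate = invert(head_to_mri)
        rms_new, matched_new = rms_dist(candidate)

        # pose-extrapolation acceleration (Besl & McKay): the plain update
        # sequence converges linearly along a nearly fixed direction in
        # 6-parameter pose space; when two successive update vectors align,
        # extrapolate toward the geometric-series limit (Aitken step,
        # capped) and keep the extrapolated pose only if it measures
        # better.  This tames the notoriously slow tangential-sliding
        # modes (e.g. pitch coupled with y/z translation on smooth heads).
        delta = pose(candidate) - pose(transform)
        norm, norm_prev = np.linalg.norm(delta), (
            np.linalg.norm(delta_prev) if delta_prev is not None else 0.0)
        if norm > 0 and norm_prev > 0:
            cosang = float(delta @ delta_prev) / (norm * norm_prev)
            ratio = norm / norm_prev
            if cosang > 0.7 and ratio < 1.0:
                gain = min(ratio / (1.0 - ratio), 1000.0)
                extrap = unpose(pose(candidate) + gain * delta)
                rms_ex, matched_ex = rms_dist(extrap)
                if rms_ex < rms_new:
                    candidate, rms_new, matched_new = extrap, rms_ex, matched_ex
                    delta = pose(candidate) - pose(transform)

        if rms_new > trace[-1] + 1e-12:
            break  # refit overshot the objective; keep the previous state
        transform, matched, delta_prev = candidate, matched_new, delta
        improvement = trace[-1] - rms_new
        trace.append(rms_new)
        if improvement < tol:
            break
    return transform, trace


def remove_outliers(points: np.ndarray,
                    surface: HeadSurface | SurfaceDistanceQuery,
                    transform: RigidTransform,
                    threshold: float = 5.0) -> np.ndarray:
    """Indices of points within ``threshold`` mm of the surface (order kept).

    Points at exactly the threshold are retained; strictly greater are
    dropped.  Raises if nothing survives (failed co-registration).
    """
    query = (surface if isinstance(surface, SurfaceDistanceQuery)
             else SurfaceDistanceQuery(surface))
    mri_pts = invert(transform).apply(np.asarray(points, dtype=float))
    dists, _ = query.query(mri_pts)
    retained = np.flatnonzero(dists <= threshold)
    if len(retained) == 0:
        raise CoregistrationError(
            f"all points are > {threshold} mm from the surface; "
            "co-registration failed")
    return retained


def auto_coregister(headshape: HeadshapePointSet, surface: HeadSurface,
                    subject_fiducial_estimates: dict,
                    config: CoregConfig | None = None) -> CoregResult:
    """Run the full automated co-registration pipeline (steps 2-5).

    ``subject_fiducial_estimates`` are nasion/lpa/rpa in the subject's MRI
    frame, typically from :func:`template_fiducials_to_subject` (step 1).

    Stage order: landmark fit -> initial ICP -> single-pass outlier
    removal -> final ICP on retained points.  Error summaries are computed
    over ALL headshape-role points with the final transform.
    """
    config = config or CoregConfig()
    for name in ("nasion", "lpa", "rpa"):
        if name not in subject_fiducial_estimates:
            raise ValueError(f"missing fiducial estimate '{name}'")
    query = SurfaceDistanceQuery(surface)
    hs_pts = headshape.headshape_points

    # step 2: landmark-only initial fit (head -> MRI source/target order:
    # digitized fiducials in head frame onto MRI-frame estimates)
    fid_head = headshape.fiducial_array()
    fid_mri = np.array([np.asarray(subject_fiducial_estimates[k], dtype=float)
                        for k in ("nasion", "lpa", "rpa")])
    lm = fit_landmarks(fid_head, fid_mri)
    t_init = invert(lm.transform)

    # step 3: initial ICP
    t1, trace1 = icp(hs_pts, query, t_init,
                     n_iter=config.n_icp_initial, tol=config.convergence_tol)

    # step 4: single-pass outlier rejection
    retained = remove_outliers(hs_pts, query, t1,
                               threshold=config.outlier_threshold)
    outliers = np.setdiff1d(np.arange(len(hs_pts)), retained)

    # step 5: final ICP on retained points
    t2, trace2 = icp(hs_pts[retained], query, t1,
                     n_iter=config.n_icp_final, tol=config.convergence_tol)
    converged = (len(trace2) <= config.n_icp_final  # stopped before the cap
                 or (len(trace2) >= 2 and trace2[-2] - trace2[-1]
                     < config.convergence_tol))

    dists, _ = query.query(invert(t2).apply(hs_pts))
    med, lo, hi = _summaries(dists)
    med_in = float(np.median(dists[retained]))
    return CoregResult(
        transform=t2, distances_all=dists,
        median_error=med, iqr_low=lo, iqr_high=hi,
        outlier_indices=outliers, converged=converged,
        iteration_trace=(tuple(trace1), tuple(trace2)),
        quality_flag=med > config.quality_threshold,
        landmark_rms=lm.rms, median_error_inliers=med_in,
        n_headshape_points=len(hs_pts),
    )


def evaluate_transform(headshape: HeadshapePointSet, surface: HeadSurface,
                       transform: RigidTransform,
                       config: CoregConfig | None = None) -> CoregResult:
    """Co-registration error for a given transform, with no fitting.

    Used to score e.g. a manually produced transform: the inverse
    transform carries the headshape points into the MRI frame and each is
    scored by its distance to the nearest surface point.
    """
    config = config or CoregConfig()
    query = SurfaceDistanceQuery(surface)
    hs_pts = headshape.headshape_points
    dists, _ = query.query(invert(transform).apply(hs_pts))
    med, lo, hi = _summaries(dists)
    return CoregResult(
        transform=transform, distances_all=dists,
        median_error=med, iqr_low=lo, iqr_high=hi,
        outlier_indices=np.array([], dtype=np.int64), converged=True,
        iteration_trace=(), quality_flag=med > config.quality_threshold,
        median_error_inliers=med, n_headshape_points=len(hs_pts),
    )
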