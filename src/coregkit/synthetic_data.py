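"""Synthetic head cohorts with known ground-truth co-registrations.

Real MEG-MRI co-registration studies need each participant's scalp
surface (from MRI) and digitized headshape (from a Polhemus-style pen).
This module fabricates both at desk scale, with the ground truth known
exactly, so the manual-vs-automated comparison can be run end-to-end and
its statistics checked against what was put in.

What is emulated
----------------
* **Scalp surface**: a triangulated closed surface built from a
  subdivided icosphere, radially shaped into an ellipsoid head with
  smooth angular-Gaussian nose and brow bumps; nasion at the nose-root,
  preauricular points at the lateral extremes (snapped to mesh vertices).
* **Headshape digitization**: points sampled by area on the scalp above
  the fiducial plane plus nose-bridge/brow patches (the regions
  technicians actually digitize, avoiding jaw and cartilage), with
  isotropic Gaussian digitizer jitter, a small fraction of stray outlier
  points, and noise-perturbed digitized fiducials; point counts follow a
  triangular distribution spanning 83-229 with median ~143.
* **Ground-truth MRI->head transforms**: sampled around a translation of
  (-2, -5, -70) mm and rotations of (14, 1, -0.5) degrees — the regime
  typical for seated MEG head coordinates — with 5 mm / 5 degree
  between-subject spread.
* **Template fiducial transfer**: the subject's "MNI-estimated"
  fiducials are the true ones plus 5 mm jitter.
* **A manual operator**: the manual transform perturbs the ground truth
  by N(0, 1 mm) per translation axis and N(0, 1 degree) per rotation
  axis, in decomposed-parameter space.

All randomness flows through explicit seeds/generators; regenerating a
cohort from its master seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .surface import HeadSurface, HeadshapePointSet, write_headshape, write_surface
from .transforms import RigidTransform, TransformParams, decompose, recompose

__all__ = [
    "SubjectSpec",
    "CohortConfig",
    "CohortSubject",
    "CohortDataset",
    "generate_head_surface",
    "generate_headshape",
    "draw_n_points",
    "sample_ground_truth_transform",
    "simulate_manual_transform",
    "generate_cohort",
]

# unit directions (MRI frame: +x right, +y anterior, +z superior) of the
# facial features, as (elevation deg above the xy-plane, applied in the
# y-z plane); the nose points anterior-inferior, the brow anterior-superior
_NOSE_ELEV_DEG = -20.0
_BROW_ELEV_DEG = 18.0
_OCCIPUT_ELEV_DEG = -5.0
_NASION_ELEV_DEG = -2.0
_NOSE_SIGMA_DEG = 10.0
_BROW_SIGMA_DEG = 18.0
_OCCIPUT_SIGMA_DEG = 25.0
#: angular radii of the digitized nose-bridge / brow patches
_BRIDGE_PATCH_DEG = 12.0
_BROW_PATCH_DEG = 20.0


def _anterior_direction(elevation_deg: float) -> np.ndarray:
    e = np.deg2rad(elevation_deg)
    return np.array([0.0, np.cos(e), np.sin(e)])


def _posterior_direction(elevation_deg: float) -> np.ndarray:
    e = np.deg2rad(elevation_deg)
    return np.array([0.0, -np.cos(e), np.sin(e)])


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to regenerate one synthetic subject.

    Geometry fields shape the head; ``seed`` drives only the stochastic
    digitization (two subjects with equal shape parameters but different
    seeds have identical geometry).
    """

    seed: int
    axes: tuple[float, float, float] = (75.0, 95.0, 110.0)  #: ellipsoid half-axes mm
    nose_amp: float = 22.0   #: nose bump amplitude mm
    brow_amp: float = 6.0    #: brow bulge amplitude mm
    occiput_amp: float = 9.0  #: occipital protuberance amplitude mm
    ground_truth: RigidTransform | None = None  #: MRI -> head
    template_jitter_sd: float = 5.0  #: mm, fiducial-transfer error
    n_points: int = 143
    noise_sd: float = 1.5    #: mm, isotropic digitizer jitter
    outlier_fraction: float = 0.05
    outlier_magnitude: float = 10.0  #: mm, outward stray-point displacement
    n_hpi: int = 4
    mesh_subdivisions: int = 4

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValueError("ellipsoid axes must be positive")
        if self.noise_sd < 0 or not 0 <= self.outlier_fraction < 1:
            raise ValueError("noise_sd >= 0 and outlier_fraction in [0, 1) required")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


# ---------------------------------------------------------------------------
# head surface
# ---------------------------------------------------------------------------

def generate_head_surface(spec: SubjectSpec) -> HeadSurface:
    """Build the subject's triangulated scalp surface with fiducials.

    Starts from a unit icosphere, computes a per-direction radius
    r(u) = ellipsoid radius + nose bump + brow bump (angular Gaussians),
    and scales each vertex.  Topology is that of the sphere (closed,
    Euler characteristic 2).  Deterministic in the shape parameters.
    """
    base = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions)
    u = np.asarray(base.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a, b, c = spec.axes
    r_ell = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2
                          + (u[:, 2] / c) ** 2)

    def bump(direction, amp, sigma_deg):
        ang = np.rad2deg(np.arccos(np.clip(u @ direction, -1.0, 1.0)))
        return amp * np.exp(-(ang / sigma_deg) ** 2)

    r = (r_ell
         + bump(_anterior_direction(_NOSE_ELEV_DEG), spec.nose_amp,
                _NOSE_SIGMA_DEG)
         + bump(_anterior_direction(_BROW_ELEV_DEG), spec.brow_amp,
                _BROW_SIGMA_DEG)
         + bump(_posterior_direction(_OCCIPUT_ELEV_DEG), spec.occiput_amp,
                _OCCIPUT_SIGMA_DEG))
    vertices = u * r[:, None]

    nas_idx = int(np.argmax(u @ _anterior_direction(_NASION_ELEV_DEG)))
    fiducials = {
        "nasion": vertices[nas_idx],
        "lpa": vertices[int(np.argmin(vertices[:, 0]))],
        "rpa": vertices[int(np.argmax(vertices[:, 0]))],
    }
    return HeadSurface(vertices, np.asarray(base.faces, dtype=np.int64),
                       fiducials=fiducials)


# ---------------------------------------------------------------------------
# headshape digitization
# ---------------------------------------------------------------------------

def _digitization_region_faces(surface: HeadSurface) -> np.ndarray:
    """Faces a technician would digitize: skull above the fiducial plane,
    plus the nose-bridge and brow patches (the nose tip stays excluded)."""
    from .surface import fiducial_frame

    frame = fiducial_frame(surface.require_fiducials())
    tri = surface.vertices[surface.triangles]
    centroids = tri.mean(axis=1)
    cz = frame.apply(centroids)[:, 2]

    udir = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    ang_bridge = np.rad2deg(np.arccos(np.clip(
        udir @ _anterior_direction(_NASION_ELEV_DEG), -1, 1)))
    ang_brow = np.rad2deg(np.arccos(np.clip(
        udir @ _anterior_direction(_BROW_ELEV_DEG), -1, 1)))
    mask = (cz > 0) | (ang_bridge < _BRIDGE_PATCH_DEG) | (ang_brow < _BROW_PATCH_DEG)
    faces = np.flatnonzero(mask)
    if len(faces) == 0:
        raise ValueError("digitization region is empty (degenerate spec)")
    return faces


def _sample_on_faces(surface: HeadSurface, faces: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    tri = surface.vertices[surface.triangles[faces]]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    pick = rng.choice(len(faces), size=n, p=areas / areas.sum())
    r1 = rng.random(n)
    r2 = rng.random(n)
    flip = r1 + r2 > 1
    r1[flip], r2[flip] = 1 - r1[flip], 1 - r2[flip]
    t = tri[pick]
    return t[:, 0] + r1[:, None] * (t[:, 1] - t[:, 0]) \
        + r2[:, None] * (t[:, 2] - t[:, 0])


def generate_headshape(surface: HeadSurface, spec: SubjectSpec,
                       rng: np.random.Generator | None = None
                       ) -> HeadshapePointSet:
    """Digitize the subject: sampled scalp points + fiducials + HPI coils.

    Points are sampled on the surface in the MRI frame, perturbed by
    isotropic Gaussian noise, a random ``outlier_fraction`` of them
    displaced radially outward by ``outlier_magnitude`` (stray pen
    readings), and finally carried into MEG head coordinates with the
    subject's ground-truth transform.  Digitized fiducials get the same
    noise; HPI coil points are sampled from the digitization region.
    """
    if spec.ground_truth is None:
        raise ValueError("spec.ground_truth transform is required")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    gt = spec.ground_truth
    faces = _digitization_region_faces(surface)

    pts = _sample_on_faces(surface, faces, spec.n_points, rng)
    pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)
    n_out = int(round(spec.outlier_fraction * spec.n_points))
    if n_out:
        idx = rng.choice(spec.n_points, size=n_out, replace=False)
        radial = pts[idx] / np.linalg.norm(pts[idx], axis=1, keepdims=True)
        pts[idx] = pts[idx] + spec.outlier_magnitude * radial

    fid = surface.require_fiducials()
    fid_pts = np.array([fid[k] for k in ("nasion", "lpa", "rpa")])
    fid_pts = fid_pts + rng.normal(0.0, spec.noise_sd, fid_pts.shape)
    hpi_pts = _sample_on_faces(surface, faces, spec.n_hpi, rng) \
        + rng.normal(0.0, spec.noise_sd, (spec.n_hpi, 3))

    all_mri = np.vstack([fid_pts, hpi_pts, pts])
    labels = np.array(["nasion", "lpa", "rpa"] + ["hpi"] * spec.n_hpi
                      + ["headshape"] * spec.n_points, dtype=object)
    return HeadshapePointSet(gt.apply(all_mri), labels)


def draw_n_points(rng: np.random.Generator, low: int = 83, mode: int = 132,
                  high: int = 229) -> int:
    """Headshape-point count: rounded triangular draw, median ~143."""
    return int(round(rng.triangular(low, mode, high)))


# ---------------------------------------------------------------------------
# transforms: ground truth and the simulated manual operator
# ---------------------------------------------------------------------------

def sample_ground_truth_transform(
        rng: np.random.Generator,
        center_translation: tuple = (-2.0, -5.0, -70.0),
        center_rotation_deg: tuple = (14.0, 1.0, -0.5),
        translation_sd: float = 5.0,
        rotation_sd_deg: float = 5.0) -> RigidTransform:
    """Draw a subject's true MRI->head transform.

    Parameters are sampled independently and normally around the centers
    (defaults reflect typical seated-MEG head transforms: large negative
    z translation, ~14 degrees of pitch) with the given between-subject
    SDs; zero SDs reproduce the central transform exactly.
    """
    t = np.asarray(center_translation, float) + rng.normal(0, translation_sd, 3)
    r = np.asarray(center_rotation_deg, float) + rng.normal(0, rotation_sd_deg, 3)
    return recompose(TransformParams(*t, *r))


def simulate_manual_transform(ground_truth: RigidTransform,
                              operator_sd_mm: float = 1.0,
                              operator_sd_deg: float = 1.0,
                              rng: np.random.Generator | None = None
                              ) -> RigidTransform:
    """A manual operator's transform: ground truth + parameter-space noise.

    Each decomposed parameter is independently perturbed: translations by
    N(0, operator_sd_mm), rotations by N(0, operator_sd_deg).  Zero SDs
    return the ground truth unchanged.
    """
    if operator_sd_mm < 0 or operator_sd_deg < 0:
        raise ValueError("operator SDs must be >= 0")
    if operator_sd_mm == 0 and operator_sd_deg == 0:
        return ground_truth
    rng = np.random.default_rng() if rng is None else rng
    p = decompose(ground_truth).as_array()
    p[:3] += rng.normal(0.0, operator_sd_mm, 3)
    p[3:] += rng.normal(0.0, operator_sd_deg, 3)
    return recompose(TransformParams(*p))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings (the study conditions)."""

    noise_sd: float = 1.5
    outlier_fraction: float = 0.05
    outlier_magnitude: float = 10.0
    template_jitter_sd: float = 5.0
    operator_sd_mm: float = 1.0
    operator_sd_deg: float = 1.0
    n_points_low: int = 83
    n_points_mode: int = 132
    n_points_high: int = 229
    base_axes: tuple[float, float, float] = (75.0, 95.0, 110.0)
    axes_rel_sd: float = 0.03      #: per-subject head-size variation
    feature_rel_sd: float = 0.15   #: per-subject nose/brow amplitude variation
    translation_sd: float = 5.0    #: between-subject transform spread, mm
    rotation_sd_deg: float = 5.0   #: between-subject transform spread, deg
    mesh_subdivisions: int = 4


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    spec: SubjectSpec
    surface: HeadSurface
    headshape: HeadshapePointSet
    ground_truth: RigidTransform
    manual_transform: RigidTransform
    fiducial_estimates: dict  #: template-transferred fiducials, MRI frame


@dataclass(frozen=True)
class CohortDataset:
    """A generated cohort; bit-identical under regeneration from its seed."""

    subjects: tuple
    master_seed: int
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.subjects)

    def to_directory(self, path: str | Path) -> None:
        """Write the on-disk layout consumed by the CLI:
        ``sub-XX/{surface.ply, fiducials.json, template_fiducials.json,
        headshape.txt, truth_trans.txt, manual_trans.txt}``."""
        import json

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        (root / "cohort.json").write_text(json.dumps({
            "master_seed": self.master_seed,
            "n_subjects": len(self.subjects),
            "config": dataclasses.asdict(self.config),
        }, indent=1))
        for sub in self.subjects:
            d = root / sub.subject_id
            d.mkdir(exist_ok=True)
            write_surface(sub.surface, d / "surface.ply")
            (d / "fiducials.json").write_text(json.dumps(
                {k: list(map(float, v)) for k, v in
                 sub.surface.fiducials.items()}, indent=1))
            (d / "template_fiducials.json").write_text(json.dumps(
                {k: list(map(float, v)) for k, v in
                 sub.fiducial_estimates.items()}, indent=1))
            write_headshape(sub.headshape, d / "headshape.txt")
            sub.ground_truth.to_file(d / "truth_trans.txt")
            sub.manual_transform.to_file(d / "manual_trans.txt")


def _make_subject(subject_id: str, seed_seq: np.random.SeedSequence,
                  cfg: CohortConfig) -> CohortSubject:
    ss_shape, ss_digitize = seed_seq.spawn(2)
    rng = np.random.default_rng(ss_shape)
    axes = tuple(np.asarray(cfg.base_axes)
                 * (1.0 + rng.normal(0, cfg.axes_rel_sd, 3)))
    nose = 22.0 * max(0.3, 1.0 + rng.normal(0, cfg.feature_rel_sd))
    brow = 6.0 * max(0.3, 1.0 + rng.normal(0, cfg.feature_rel_sd))
    gt = sample_ground_truth_transform(
        rng, translation_sd=cfg.translation_sd,
        rotation_sd_deg=cfg.rotation_sd_deg)
    n_points = draw_n_points(rng, cfg.n_points_low, cfg.n_points_mode,
                             cfg.n_points_high)
    manual = simulate_manual_transform(gt, cfg.operator_sd_mm,
                                       cfg.operator_sd_deg, rng)

    spec = SubjectSpec(
        seed=int(ss_digitize.generate_state(1)[0] % 2**31),
        axes=axes, nose_amp=nose, brow_amp=brow, ground_truth=gt,
        template_jitter_sd=cfg.template_jitter_sd, n_points=n_points,
        noise_sd=cfg.noise_sd, outlier_fraction=cfg.outlier_fraction,
        outlier_magnitude=cfg.outlier_magnitude,
        mesh_subdivisions=cfg.mesh_subdivisions)
    surface = generate_head_surface(spec)
    headshape = generate_headshape(surface, spec)
    fid = surface.require_fiducials()
    estimates = {k: fid[k] + rng.normal(0, cfg.template_jitter_sd, 3)
                 for k in ("nasion", "lpa", "rpa")}
    return CohortSubject(subject_id, spec, surface, headshape, gt, manual,
                         estimates)


def generate_cohort(n_subjects: int, master_seed: int,
                    config: CohortConfig | None = None,
                    out_dir: str | Path | None = None) -> CohortDataset:
    """Generate ``n_subjects`` independent synthetic subjects.

    Per-subject random streams are spawned from the master seed, so any
    subject can be regenerated in isolation and the whole cohort is
    reproducible bit-for-bit.  When ``out_dir`` is given the on-disk
    layout is written as well.
    """
    if n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    config = config or CohortConfig()
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    subjects = tuple(
        _make_subject(f"sub-{i:02d}", child, config)
        for i, child in enumerate(children))
    cohort = CohortDataset(subjects, master_seed, config)
    if out_dir is not None:
        cohort.to_directory(out_dir)
    return cohort
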