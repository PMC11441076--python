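"""Session-to-reference registration via closed-form absolute orientation.

Weekly imaging sessions of the same cortical field differ by a small
rotation, translation and near-unity uniform scale (slow atrophy).  A
similarity transform is estimated from paired fiducial nuclei with the
closed-form least-squares solution of the absolute-orientation problem
(Horn / Umeyama): given paired point sets ``p_i`` (moving) and ``q_i``
(reference), find ``s, R, t`` minimising ``sum_i || s R p_i + t - q_i ||^2``
with ``R`` a proper rotation.  Reflections are excluded by construction.

All later weeks are mapped into the week-1 frame and the registered
sessions are then cropped to the intersection of their bounding boxes so
that every analysed nucleus was observable in every week.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import SessionCloud
from .imaging import DEFAULT_VOXEL_SIZE_UM


class DegenerateFiducialsError(ValueError):
    """Fiducial configuration does not determine a similarity transform."""


class EmptyOverlapError(ValueError):
    """Registered session bounding boxes have no common intersection."""


@dataclass
class SimilarityTransform:
    """Uniform-scale rigid map ``x -> scale * rotation @ x + translation``."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.scale = float(self.scale)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=r_inv,
            translation=-(r_inv @ self.translation) / self.scale,
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
        )

    # ------------------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation": [float(v) for v in self.rotation.ravel()],  # row-major
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(d["scale"], np.asarray(d["rotation"]).reshape(3, 3), d["translation"])


@dataclass
class FiducialSet:
    """Paired landmark coordinates: ``moving`` maps onto ``reference``."""

    reference: np.ndarray
    moving: np.ndarray

    def __post_init__(self) -> None:
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.reference.shape != self.moving.shape or self.reference.shape[1] != 3:
            raise ValueError("reference and moving must be matching (n, 3) arrays")

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass
class RegistrationReport:
    """Per-fiducial residuals of a fitted transform, in um and voxel units."""

    residuals_um: np.ndarray
    rms_um: float
    rms_voxels: float
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def to_dict(self) -> dict:
        return {
            "residuals_um": [float(v) for v in self.residuals_um],
            "rms_um": float(self.rms_um),
            "rms_voxels": float(self.rms_voxels),
            "voxel_size_um": list(self.voxel_size_um),
        }


def estimate_transform(fiducials: FiducialSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping moving onto reference points.

    Uses the SVD form of the closed-form absolute-orientation solution with
    isotropic scale.  Requires at least 3 non-collinear pairs; a reflection
    is never returned (the nearest proper rotation is selected instead).
    """
    if fiducials.n < 3:
        raise DegenerateFiducialsError("at least 3 fiducial pairs are required")
    p = fiducials.moving
    q = fiducials.reference
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    x = p - mu_p
    y = q - mu_q
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFiducialsError("fiducials are collinear (or coincident)")
    cov = y.T @ x / fiducials.n
    u, d, vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(3)
    flip[-1] = sgn if sgn != 0 else 1.0
    rotation = u @ np.diag(flip) @ vt
    var_p = (x**2).sum() / fiducials.n
    scale = float((d * flip).sum() / var_p)
    translation = mu_q - scale * rotation @ mu_p
    return SimilarityTransform(scale, rotation, translation)


def registration_report(
    transform: SimilarityTransform,
    fiducials: FiducialSet,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
) -> RegistrationReport:
    """Residual diagnostics of ``transform`` on a fiducial set."""
    delta = transform.apply(fiducials.moving) - fiducials.reference
    residuals = np.linalg.norm(delta, axis=1)
    rms = float(np.sqrt(np.mean(residuals**2)))
    delta_vox = delta / np.asarray(voxel_size_um, dtype=float)
    rms_vox = float(np.sqrt(np.mean(np.sum(delta_vox**2, axis=1))))
    return RegistrationReport(residuals, rms, rms_vox, tuple(voxel_size_um))


def apply_transform(cloud: SessionCloud, transform: SimilarityTransform) -> SessionCloud:
    """Map every centroid (and the field bounds) through ``transform``.

    Bounds become the axis-aligned box of the transformed field corners.
    """
    lo, hi = cloud.bounds
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    mapped = transform.apply(corners)
    new_bounds = np.stack([mapped.min(axis=0), mapped.max(axis=0)])
    out = cloud.subset(np.arange(cloud.n))
    out.xyz = transform.apply(cloud.xyz) if cloud.n else cloud.xyz.copy()
    out.bounds = new_bounds
    return out


def crop_to_overlap(clouds: list[SessionCloud]) -> list[SessionCloud]:
    """Restrict registered sessions to the intersection of their bounds.

    Only nuclei inside the common box (inclusive) are kept, and every
    returned cloud carries the intersection as its bounds.
    """
    if len(clouds) < 2:
        raise ValueError("need at least 2 clouds to crop to overlap")
    lo = np.max([c.bounds[0] for c in clouds], axis=0)
    hi = np.min([c.bounds[1] for c in clouds], axis=0)
    if np.any(lo >= hi):
        raise EmptyOverlapError("session bounding boxes do not overlap")
    out = []
    for c in clouds:
        inside = np.all((c.xyz >= lo) & (c.xyz <= hi), axis=1)
        cc = c.subset(inside)
        cc.bounds = np.stack([lo, hi])
        out.append(cc)
    return out


def _ordered_fiducials(cloud: SessionCloud) -> tuple[np.ndarray, np.ndarray]:
    """Fiducial ids and coordinates sorted by id (the shared landmark list)."""
    fid = cloud.fiducial_cloud()
    order = np.argsort(fid.ids)
    return fid.ids[order], fid.xyz[order]


def register_sessions(
    sessions: list[SessionCloud],
    reference_index: int = 0,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[list[SessionCloud], list[SimilarityTransform], list[RegistrationReport]]:
    """Map all sessions into the reference session's frame via fiducials.

    Fiducial correspondence follows the shared landmark ids (the
    hand-curated stable-ID subset); every session must flag the same ids.
    """
    ref_ids, ref_xyz = _ordered_fiducials(sessions[reference_index])
    if len(ref_ids) < 3:
        raise DegenerateFiducialsError("reference session has fewer than 3 fiducials")
    registered, transforms, reports = [], [], []
    for i, sess in enumerate(sessions):
        if i == reference_index:
            t = SimilarityTransform.identity()
            fids = FiducialSet(ref_xyz, ref_xyz)
        else:
            ids, xyz = _ordered_fiducials(sess)
            if not np.array_equal(ids, ref_ids):
                raise ValueError(f"session week {sess.week}: fiducial ids differ from reference")
            fids = FiducialSet(ref_xyz, xyz)
            t = estimate_transform(fids)
        registered.append(apply_transform(sess, t))
        transforms.append(t)
        reports.append(registration_report(t, fids, voxel_size_um))
    return registered, transforms, reports


def save_transforms(transforms: list[SimilarityTransform], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in transforms], indent=1))


def load_transforms(path: str | Path) -> list[SimilarityTransform]:
    return [SimilarityTransform.from_dict(d) for d in json.loads(Path(path).read_text())]
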