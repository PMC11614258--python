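"""Registration of hyperspectral images to 3-D meshes and surface-normal maps.

Because the imager sits at a fixed height above a linear translation
stage, the acquisition geometry is effectively orthographic with a
constant scale across images.  Pose estimation is therefore a
weak-perspective similarity fit: paired landmarks (pixel coordinates in
the image, 3-D coordinates on the mesh) determine a rotation, a single
scale, and a 2-D translation by least squares.

With the pose in hand, the mesh is rasterised into the image plane with
an orthographic depth buffer, and each covered pixel receives the pitch
and roll of the frontmost surface normal expressed in the camera frame:

* camera frame: x -> image column (right), y -> image row (down),
  z -> toward the camera;
* ``roll  = atan2(-n_x, n_z)``: positive when the surface faces left of
  the camera, in [-pi, pi];
* ``pitch = atan2(-n_y, n_z)``: positive when the surface faces up.

Angle maps enable angle-resolved color analysis (binning sampled spectra
by the pitch of the underlying surface), which matters because plumage —
especially iridescent plumage — is strongly non-Lambertian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "Pose",
    "SurfaceNormalMap",
    "estimate_pose",
    "render_normals",
    "bin_by_pitch",
]


@dataclass
class LandmarkSet:
    """Paired image (row, col) and mesh (X, Y, Z) landmark coordinates."""

    image_points: np.ndarray  # (n, 2) as (row, col)
    mesh_points: np.ndarray  # (n, 3)
    names: list | None = None

    def __post_init__(self) -> None:
        self.image_points = np.atleast_2d(np.asarray(self.image_points, float))
        self.mesh_points = np.atleast_2d(np.asarray(self.mesh_points, float))
        if len(self.image_points) != len(self.mesh_points):
            raise ValueError("image and mesh landmark counts differ")
        if len(self.image_points) < 3:
            raise ValueError("at least 3 landmark pairs are required")

    def __len__(self) -> int:
        return len(self.image_points)

    def to_csv(self, path) -> None:
        import pandas as pd

        names = self.names or [f"p{i}" for i in range(len(self))]
        pd.DataFrame({
            "name": names,
            "row": self.image_points[:, 0], "col": self.image_points[:, 1],
            "X": self.mesh_points[:, 0], "Y": self.mesh_points[:, 1],
            "Z": self.mesh_points[:, 2],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["row", "col"]].to_numpy(float),
                   df[["X", "Y", "Z"]].to_numpy(float),
                   names=list(df.get("name", [])) or None)


@dataclass
class Pose:
    """Orthographic similarity transform mesh -> image.

    ``project`` maps mesh points X to image (col, row) = s (R X)_{0:2} + t;
    the camera-frame depth s (R X)_2 increases toward the camera.
    """

    rotation: np.ndarray  # (3, 3)
    scale: float
    translation: np.ndarray  # (2,) in (col, row) order
    rmse: float = 0.0

    def camera_frame(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.atleast_2d(points) @ self.rotation.T)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project mesh points to (col, row) pixel coordinates."""
        cam = self.camera_frame(points)
        return cam[:, :2] + self.translation


@dataclass
class SurfaceNormalMap:
    """Per-pixel roll/pitch (radians, [-pi, pi]) with a validity mask."""

    roll: np.ndarray
    pitch: np.ndarray
    valid: np.ndarray

    def angles_at(self, locations) -> np.ndarray:
        """(roll, pitch) at integer pixel locations (row, col); NaN where
        the map is invalid."""
        locations = np.atleast_2d(np.asarray(locations, int))
        out = np.full((len(locations), 2), np.nan)
        r, c = locations[:, 0], locations[:, 1]
        ok = ((0 <= r) & (r < self.valid.shape[0])
              & (0 <= c) & (c < self.valid.shape[1]))
        okv = ok.copy()
        okv[ok] = self.valid[r[ok], c[ok]]
        out[okv, 0] = self.roll[r[okv], c[okv]]
        out[okv, 1] = self.pitch[r[okv], c[okv]]
        return out


def estimate_pose(landmarks: LandmarkSet) -> Pose:
    """Least-squares orthographic similarity fit from landmark pairs.

    The generic branch (>= 4 non-coplanar mesh points) fits an affine
    2x3 map and projects it onto the nearest scaled rotation via SVD;
    exactly-similar input is recovered exactly.  Coplanar configurations
    (including the 3-point minimum) fall back to an in-plane 2-D
    similarity fit, where the out-of-plane tilt is unobservable.
    Collinear landmarks are degenerate and rejected.
    """
    X = landmarks.mesh_points
    # image (col, row) -> (x, y) in camera frame
    U = landmarks.image_points[:, ::-1]
    Xc = X - X.mean(axis=0)
    svals = np.linalg.svd(Xc, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("landmarks are collinear; pose is degenerate")
    coplanar = len(X) < 4 or svals[2] < 1e-9 * svals[0]

    if not coplanar:
        A = np.hstack([X, np.ones((len(X), 1))])
        coef, *_ = np.linalg.lstsq(A, U, rcond=None)
        M = coef[:3].T  # (2, 3)
        uu, ss, vt = np.linalg.svd(M, full_matrices=False)
        scale = float(ss.mean())
        R12 = uu @ vt  # orthonormal rows
        r3 = np.cross(R12[0], R12[1])
        R = np.vstack([R12, r3])
        t = coef[3]
    else:
        # plane basis from the mesh points, then 2-D similarity Procrustes
        _, _, vt = np.linalg.svd(Xc)
        e1, e2 = vt[0], vt[1]
        P = Xc @ np.vstack([e1, e2]).T  # (n, 2) plane coordinates
        Uc = U - U.mean(axis=0)
        H = Uc.T @ P
        uu, ss, vvt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(uu @ vvt))
        Dm = np.diag([1.0, d])
        Q = uu @ Dm @ vvt
        denom = (P ** 2).sum()
        scale = float((ss * np.array([1.0, d])).sum() / denom) if denom else 1.0
        r1 = Q[0, 0] * e1 + Q[0, 1] * e2
        r2 = Q[1, 0] * e1 + Q[1, 1] * e2
        r3 = np.cross(r1, r2)
        R = np.vstack([r1, r2, r3])
        t = U.mean(axis=0) - scale * (R @ X.mean(axis=0))[:2]

    pose = Pose(rotation=R, scale=scale, translation=t)
    resid = pose.project(X) - U
    pose.rmse = float(np.sqrt((resid ** 2).mean()))
    return pose


def _face_data(mesh):
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    return vertices, faces


def render_normals(mesh, pose: Pose, shape,
                   use_vertex_normals: bool = False) -> SurfaceNormalMap:
    """Orthographic depth-buffer rasterisation of the mesh into the image.

    Each covered pixel takes the frontmost triangle's normal (or the
    barycentric interpolation of vertex normals when
    ``use_vertex_normals=True``, which is markedly more accurate on
    curved surfaces), transformed to the camera frame.  Background
    pixels are flagged invalid, never silently zero.
    """
    lines, samples = int(shape[0]), int(shape[1])
    vertices, faces = _face_data(mesh)
    cam = pose.camera_frame(vertices)
    uv = cam[:, :2] + pose.translation  # (col, row)
    depth_v = cam[:, 2]

    R = pose.rotation
    face_n = np.asarray(mesh.face_normals, dtype=float) @ R.T
    if use_vertex_normals:
        vert_n = np.asarray(mesh.vertex_normals, dtype=float) @ R.T

    depth = np.full((lines, samples), -np.inf)
    normal = np.zeros((lines, samples, 3))
    valid = np.zeros((lines, samples), dtype=bool)

    cols = uv[:, 0]
    rows = uv[:, 1]
    tri_cols = cols[faces]  # (n_faces, 3)
    tri_rows = rows[faces]
    # cull faces fully outside the image
    keep = ~((tri_cols.max(axis=1) < 0) | (tri_cols.min(axis=1) > samples - 1)
             | (tri_rows.max(axis=1) < 0) | (tri_rows.min(axis=1) > lines - 1))
    if not keep.any():
        logger.warning("render_normals: mesh projects entirely off-image")
        return SurfaceNormalMap(np.zeros((lines, samples)),
                                np.zeros((lines, samples)), valid)

    for fi in np.flatnonzero(keep):
        c = tri_cols[fi]
        r = tri_rows[fi]
        c0 = max(int(np.floor(c.min())), 0)
        c1 = min(int(np.ceil(c.max())), samples - 1)
        r0 = max(int(np.floor(r.min())), 0)
        r1 = min(int(np.ceil(r.max())), lines - 1)
        if c1 < c0 or r1 < r0:
            continue
        px, py = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        # barycentric coordinates in (col, row) space
        x1, x2, x3 = c
        y1, y2, y3 = r
        det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(det) < 1e-12:
            continue
        w1 = ((y2 - y3) * (px - x3) + (x3 - x2) * (py - y3)) / det
        w2 = ((y3 - y1) * (px - x3) + (x1 - x3) * (py - y3)) / det
        w3 = 1.0 - w1 - w2
        inside = (w1 >= -1e-9) & (w2 >= -1e-9) & (w3 >= -1e-9)
        if not inside.any():
            continue
        dvals = (w1 * depth_v[faces[fi, 0]] + w2 * depth_v[faces[fi, 1]]
                 + w3 * depth_v[faces[fi, 2]])
        sub_r = py[inside]
        sub_c = px[inside]
        dv = dvals[inside]
        closer = dv > depth[sub_r, sub_c]
        if not closer.any():
            continue
        sr, sc, dvc = sub_r[closer], sub_c[closer], dv[closer]
        depth[sr, sc] = dvc
        if use_vertex_normals:
            nv = (w1[inside][closer, None] * vert_n[faces[fi, 0]]
                  + w2[inside][closer, None] * vert_n[faces[fi, 1]]
                  + w3[inside][closer, None] * vert_n[faces[fi, 2]])
            nv /= np.linalg.norm(nv, axis=1, keepdims=True)
            normal[sr, sc] = nv
        else:
            normal[sr, sc] = face_n[fi]
        valid[sr, sc] = True

    n_x, n_y, n_z = normal[..., 0], normal[..., 1], normal[..., 2]
    roll = np.where(valid, np.arctan2(-n_x, n_z), 0.0)
    pitch = np.where(valid, np.arctan2(-n_y, n_z), 0.0)
    return SurfaceNormalMap(roll=roll, pitch=pitch, valid=valid)


@dataclass
class PitchBin:
    """Median +- MAD reflectance of the samples in one pitch bin."""

    lo: float
    hi: float
    count: int
    median: np.ndarray
    mad: np.ndarray


def bin_by_pitch(sampleset, normals: SurfaceNormalMap, bin_edges) -> list:
    """Group sampled spectra by the pitch of their surface normal.

    Each retained sample lands in exactly one bin; samples whose window
    centre has no valid normal are dropped (and counted in the log).
    Empty bins are omitted with a warning.  Returns a list of
    :class:`PitchBin` ordered by pitch.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    locs = sampleset.meta[["row", "col"]].to_numpy(int)
    angles = normals.angles_at(locs)
    pitch = angles[:, 1]
    ok = ~np.isnan(pitch)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("bin_by_pitch: dropped %d samples without a valid normal",
                    n_dropped)
    pitch = pitch[ok]
    spectra = sampleset.spectra[ok]
    which = np.digitize(pitch, edges) - 1
    bins = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            logger.warning("bin_by_pitch: bin [%.3f, %.3f) is empty, omitted",
                           edges[b], edges[b + 1])
            continue
        block = spectra[sel]
        med = np.median(block, axis=0)
        mad = np.median(np.abs(block - med), axis=0)
        bins.append(PitchBin(float(edges[b]), float(edges[b + 1]),
                             int(sel.sum()), med, mad))
    return bins
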