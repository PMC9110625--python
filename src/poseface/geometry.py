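"""Ellipsoidal head model: quadric surface, pose, weak-perspective projection,
and pose estimation from tracked 2D points.

The head is modelled as an ellipsoid with semi-axes (a, b, c).  In homogeneous
coordinates a point X = (x, y, z, 1) lies on the surface iff X^T E0 X = 0 with
E0 = diag(b^2 c^2, a^2 c^2, a^2 b^2, -a^2 b^2 c^2).  A rigid head pose is an
intrinsic yaw-pitch-roll rotation about the ellipsoid center plus a
translation; yaw turns the head about the vertical image axis (y, pointing
down), pitch about x, roll about the optical axis z.  The camera is weak
perspective: after the rigid motion the (x, y) coordinates are scaled by a
constant pixels-per-model-unit factor and shifted by the principal point, so
depth (tz) leaves the image unchanged.

Pose estimation minimizes the sum of squared reprojection residuals
sum_j || project(Y_j, pose) - alpha_j ||^2 over the tracked feature points
alpha_j, by damped (Levenberg-Marquardt) least squares started from the
previous frame's pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "Ellipsoid",
    "Pose",
    "AnchorPoint",
    "Camera",
    "PoseEstimate",
    "ellipsoid_quadric",
    "on_surface",
    "rotation_matrix",
    "project",
    "estimate_pose",
    "default_anchors",
    "read_anchors_csv",
    "write_anchors_csv",
    "read_poses_csv",
    "write_poses_csv",
]

# Euler convention: intrinsic rotations applied yaw (about y), pitch (about x),
# roll (about z).  Image axes: x = column rightward, y = row downward.
_EULER_ORDER = "YXZ"


def ellipsoid_quadric(a: float, b: float, c: float) -> np.ndarray:
    """Homogeneous quadric matrix of an axis-aligned, centered ellipsoid.

    Returns diag(b^2 c^2, a^2 c^2, a^2 b^2, -a^2 b^2 c^2); surface points
    X = (x, y, z, 1) satisfy X^T E0 X = 0.
    """
    if not (a > 0 and b > 0 and c > 0):
        raise InvalidParameterError(f"semi-axes must be positive, got {(a, b, c)}")
    a2, b2, c2 = a * a, b * b, c * c
    return np.diag([b2 * c2, a2 * c2, a2 * b2, -a2 * b2 * c2]).astype(float)


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid head model with semi-axes (a, b, c) in model units."""

    a: float = 0.7
    b: float = 1.0
    c: float = 0.8

    def __post_init__(self) -> None:
        ellipsoid_quadric(self.a, self.b, self.c)  # validates

    @property
    def E0(self) -> np.ndarray:
        return ellipsoid_quadric(self.a, self.b, self.c)

    def surface_point(self, theta: float, phi: float) -> np.ndarray:
        """Parametric surface point: theta = longitude, phi = latitude."""
        return np.array(
            [
                self.a * math.cos(phi) * math.sin(theta),
                self.b * math.sin(phi),
                self.c * math.cos(phi) * math.cos(theta),
            ]
        )

    def outward_normal(self, point: np.ndarray) -> np.ndarray:
        """Unnormalized outward surface normal at a model-frame point."""
        p = np.asarray(point, dtype=float)
        return p / np.array([self.a**2, self.b**2, self.c**2])


def on_surface(X: np.ndarray, ellipsoid: Ellipsoid, tol: float = 1e-9) -> bool:
    """True iff the homogeneous point X lies on the ellipsoid surface.

    The residual |X^T E0 X| is compared against ``tol * max(1, |E0| scale)``
    so the test is meaningful across ellipsoid sizes.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (4,) or X[3] != 1.0:
        raise InvalidInputError("X must be homogeneous: 4 components with last = 1")
    E0 = ellipsoid.E0
    scale = max(1.0, abs(E0[3, 3]))
    return bool(abs(X @ E0 @ X) <= tol * scale)


def _wrap_angle(angle: float) -> float:
    """Wrap to (-pi, pi]."""
    wrapped = (angle + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if wrapped == -math.pi else wrapped


@dataclass(frozen=True)
class Pose:
    """Rigid head pose: intrinsic yaw-pitch-roll (radians) plus translation.

    The pose maps a model-frame point Y to the camera frame as R @ Y + t.
    Angles are stored wrapped to (-pi, pi]; ``t`` is the frame index.
    """

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "yaw", _wrap_angle(self.yaw))
        object.__setattr__(self, "pitch", _wrap_angle(self.pitch))
        object.__setattr__(self, "roll", _wrap_angle(self.roll))

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.yaw, self.pitch, self.roll)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    def apply(self, Y: np.ndarray) -> np.ndarray:
        """Transform model-frame point(s) into the camera frame."""
        Y = np.asarray(Y, dtype=float)
        return Y @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """Pose applying ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        t = self.rotation @ other.translation + self.translation
        yaw, pitch, roll = Rotation.from_matrix(R).as_euler(_EULER_ORDER)
        return Pose(yaw, pitch, roll, t[0], t[1], t[2], self.t)

    def inverse(self) -> "Pose":
        R = self.rotation.T
        t = -R @ self.translation
        yaw, pitch, roll = Rotation.from_matrix(R).as_euler(_EULER_ORDER)
        return Pose(yaw, pitch, roll, t[0], t[1], t[2], self.t)

    def params(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll, self.tx, self.ty, self.tz])


def rotation_matrix(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """3x3 rotation for intrinsic yaw (y axis), pitch (x), roll (z)."""
    return Rotation.from_euler(_EULER_ORDER, [yaw, pitch, roll]).as_matrix()


@dataclass(frozen=True)
class AnchorPoint:
    """A tracked feature's resting position on the ellipsoid surface."""

    id: int
    position: np.ndarray  # model-frame (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise InvalidInputError("anchor position must be a 3-vector")


@dataclass(frozen=True)
class Camera:
    """Weak-perspective camera: pixel = (s*x + cx, s*y + cy) after the pose."""

    scale: float = 48.0
    cx: float = 64.0
    cy: float = 64.0
    kind: str = "weak-perspective"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidParameterError(f"camera scale must be > 0, got {self.scale}")
        if self.kind != "weak-perspective":
            raise InvalidParameterError(f"unsupported projection kind {self.kind!r}")


def project(Y: np.ndarray, pose: Pose, cam: Camera) -> np.ndarray:
    """Project model-frame 3D point(s) to pixel coordinates.

    Accepts a single (3,) point or an (n, 3) stack; returns (2,) or (n, 2).
    """
    p = pose.apply(Y)
    xy = p[..., :2]
    return cam.scale * xy + np.array([cam.cx, cam.cy])


@dataclass
class PoseEstimate:
    """Result of :func:`estimate_pose`."""

    pose: Pose
    residual: float  # sum of squared reprojection residuals, px^2
    converged: bool
    n_iter: int
    per_point_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def _reprojection_residuals(
    params: np.ndarray, tz: float, anchors: np.ndarray, tracked: np.ndarray, cam: Camera
) -> np.ndarray:
    pose = Pose(*params[:3], params[3], params[4], tz)
    return (project(anchors, pose, cam) - tracked).ravel()


def estimate_pose(
    tracked: np.ndarray,
    anchors: list[AnchorPoint] | np.ndarray,
    cam: Camera,
    init: Pose,
    *,
    max_iter: int = 100,
    step_tol: float = 1e-8,
) -> PoseEstimate:
    """Recover the head pose that minimizes reprojection error.

    Damped least squares (Levenberg-Marquardt) over (yaw, pitch, roll, tx, ty)
    with a central-difference Jacobian, started at ``init`` (normally the
    previous frame's estimate).  ``tz`` is carried through unchanged: under
    weak perspective depth translation is unobservable.  Non-convergence is
    reported through the ``converged`` flag, not an exception.
    """
    if isinstance(anchors, np.ndarray):
        Y = np.asarray(anchors, dtype=float)
    else:
        Y = np.stack([a.position for a in anchors])
    tracked = np.asarray(tracked, dtype=float)
    if tracked.ndim != 2 or tracked.shape[1] != 2 or tracked.shape[0] != Y.shape[0]:
        raise InvalidInputError("tracked must be (n, 2) matching the anchor count")
    if Y.shape[0] < 3:
        raise InsufficientDataError("pose estimation needs >= 3 correspondences")
    rank = np.linalg.matrix_rank(Y[1:] - Y[0], tol=1e-12)
    if Y.shape[0] == 3 and rank < 2:
        raise InsufficientDataError("3 correspondences must be non-collinear")

    p = init.params()[:5].copy()
    tz = init.tz
    r = _reprojection_residuals(p, tz, Y, tracked, cam)
    cost = float(r @ r)
    lam = 1e-3
    converged = False
    it = 0
    h = 1e-6
    for it in range(1, max_iter + 1):
        # central-difference Jacobian
        J = np.empty((r.size, p.size))
        for k in range(p.size):
            dp = np.zeros_like(p)
            dp[k] = h
            rp = _reprojection_residuals(p + dp, tz, Y, tracked, cam)
            rm = _reprojection_residuals(p - dp, tz, Y, tracked, cam)
            J[:, k] = (rp - rm) / (2.0 * h)
        JTJ = J.T @ J
        g = J.T @ r
        step = None
        for _ in range(20):  # adapt damping until the step reduces the cost
            A = JTJ + lam * np.diag(np.maximum(np.diag(JTJ), 1e-12))
            try:
                candidate = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_new = _reprojection_residuals(p + candidate, tz, Y, tracked, cam)
            cost_new = float(r_new @ r_new)
            if cost_new <= cost:
                step = candidate
                r, cost = r_new, cost_new
                lam = max(lam / 10.0, 1e-12)
                break
            lam *= 10.0
        if step is None:
            break
        p = p + step
        if float(np.linalg.norm(step)) < step_tol:
            converged = True
            break
    else:
        it = max_iter
    if not converged and cost < 1e-20:
        converged = True  # already at a (numerical) global minimum

    pose = Pose(p[0], p[1], p[2], p[3], p[4], tz, init.t)
    per_point = np.linalg.norm(r.reshape(-1, 2), axis=1)
    return PoseEstimate(pose=pose, residual=cost, converged=converged, n_iter=it,
                        per_point_residuals=per_point)


# Default anchor layout: 24 feature points on the front hemisphere, grouped
# around the regions whose muscles deform most under expressions (eyes, brows,
# cheeks, mouth, chin, nose).  Coordinates are fractions of the semi-axes in
# the frontal plane; depth follows the ellipsoid surface (z < 0 faces the
# camera).
_ANCHOR_LAYOUT: tuple[tuple[float, float], ...] = (
    # left eye (viewer's left)
    (-0.45, -0.28), (-0.25, -0.28), (-0.35, -0.20), (-0.35, -0.36),
    # right eye
    (0.45, -0.28), (0.25, -0.28), (0.35, -0.20), (0.35, -0.36),
    # brows
    (-0.35, -0.48), (0.35, -0.48),
    # nose
    (0.0, 0.0),
    # cheeks
    (-0.55, 0.10), (-0.45, 0.25), (-0.30, 0.15),
    (0.55, 0.10), (0.45, 0.25), (0.30, 0.15),
    # mouth
    (-0.30, 0.45), (-0.12, 0.50), (0.0, 0.52), (0.12, 0.50), (0.30, 0.45),
    # chin + forehead
    (0.0, 0.70), (0.0, -0.62),
)


def default_anchors(ellipsoid: Ellipsoid, n: int = 24) -> list[AnchorPoint]:
    """N feature anchors on the front of the ellipsoid (default N = 24)."""
    if not 1 <= n <= len(_ANCHOR_LAYOUT):
        raise InvalidParameterError(f"n must be in [1, {len(_ANCHOR_LAYOUT)}]")
    anchors = []
    for j, (fx, fy) in enumerate(_ANCHOR_LAYOUT[:n], start=1):
        x = fx * ellipsoid.a
        y = fy * ellipsoid.b
        inside = 1.0 - (x / ellipsoid.a) ** 2 - (y / ellipsoid.b) ** 2
        z = -ellipsoid.c * math.sqrt(max(inside, 0.0))
        anchors.append(AnchorPoint(id=j, position=np.array([x, y, z])))
    return anchors


# --- CSV interfaces -------------------------------------------------------

def write_anchors_csv(path, anchors: list[AnchorPoint]) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"id": a.id, "X": a.position[0], "Y": a.position[1], "Z": a.position[2]}
         for a in anchors]
    ).to_csv(path, index=False)


def read_anchors_csv(path) -> list[AnchorPoint]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return [AnchorPoint(id=int(r.id), position=np.array([r.X, r.Y, r.Z]))
            for r in df.itertuples()]


def write_poses_csv(path, poses: list[Pose]) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"frame": p.t, "yaw": p.yaw, "pitch": p.pitch, "roll": p.roll,
          "tx": p.tx, "ty": p.ty, "tz": p.tz} for p in poses]
    ).to_csv(path, index=False)


def read_poses_csv(path) -> list[Pose]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return [Pose(r.yaw, r.pitch, r.roll, r.tx, r.ty, r.tz, int(r.frame))
            for r in df.itertuples()]
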