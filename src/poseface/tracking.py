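"""Pyramidal window-based optical-flow tracking of facial feature points.

Under the brightness-constancy assumption a pixel keeps its luminance between
consecutive frames, I(x+u, y+v, t+1) = I(x, y, t).  Linearizing over a
(2w+1)^2 window gives the normal equations C_k (u, v)^T + D_k = 0 with

    C_k = [[sum Ix^2, sum Ix Iy], [sum Ix Iy, sum Iy^2]],
    D_k = (sum Ix It, sum Iy It)^T,

solved as (u, v) = -C_k^{-1} D_k whenever the window carries enough texture
(minimum eigenvalue of C_k above a threshold).  Large motions are handled
coarse-to-fine on an image pyramid built with the 1/4-1/8-1/16 smoothing
kernel: the displacement is estimated at the deepest level in Newton-Raphson
iterations, doubled as the initial guess one level up, and the final
displacement is the composition sum_j 2^j d^j over levels.

Features whose window loses texture or whose post-solve residual grows are
marked lost and excluded from the remainder of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Frame",
    "ImagePyramid",
    "FlowWindow",
    "FeatureTrack",
    "TrackingConfig",
    "build_pyramid",
    "gradients",
    "make_flow_window",
    "solve_flow_window",
    "pyramidal_flow",
    "track_sequence",
    "load_frame",
    "write_tracks_csv",
    "read_tracks_csv",
]


@dataclass(frozen=True)
class Frame:
    """A grayscale frame with luminance in [0, 1]."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidInputError("frame must be a 2D luminance array")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_pixels(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.pixels
    px = np.asarray(frame, dtype=float)
    if px.ndim != 2:
        raise InvalidInputError("frame must be a 2D luminance array")
    return px


@dataclass
class ImagePyramid:
    """Multi-resolution stack; level 0 is the original frame."""

    levels: list[np.ndarray]

    @property
    def j_max(self) -> int:
        return len(self.levels) - 1


def _pyramid_reduce(level: np.ndarray) -> np.ndarray:
    """One pyramid step: smooth with the 1/4, 1/8, 1/16 kernel, sample even pixels.

    Border samples use reflect padding.
    """
    h, w = level.shape
    P = np.pad(level, 1, mode="reflect")
    nh, nw = (h + 1) // 2, (w + 1) // 2
    # padded index of original (r, c) is (r+1, c+1); centers at even originals
    rows = 2 * np.arange(nh) + 1
    cols = 2 * np.arange(nw) + 1
    r, c = np.ix_(rows, cols)
    center = P[r, c]
    edges = P[r - 1, c] + P[r + 1, c] + P[r, c - 1] + P[r, c + 1]
    corners = P[r - 1, c - 1] + P[r + 1, c + 1] + P[r + 1, c - 1] + P[r - 1, c + 1]
    return 0.25 * center + 0.125 * edges + 0.0625 * corners


def build_pyramid(frame, j_max: int = 3) -> ImagePyramid:
    """Build an image pyramid with ``j_max + 1`` levels."""
    px = _as_pixels(frame)
    if j_max < 0:
        raise InvalidParameterError("j_max must be >= 0")
    if min(px.shape) < 2**j_max:
        raise InvalidParameterError(
            f"frame of shape {px.shape} too small for j_max={j_max}"
        )
    levels = [px]
    for _ in range(j_max):
        levels.append(_pyramid_reduce(levels[-1]))
    return ImagePyramid(levels=levels)


def gradients(frame_t, frame_t1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial gradients of frame_t (central differences) and temporal difference.

    Returns (I_x, I_y, I_t) with x the column direction and y the row direction.
    """
    a = _as_pixels(frame_t)
    b = _as_pixels(frame_t1)
    if a.shape != b.shape:
        raise InvalidInputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    I_y, I_x = np.gradient(a)
    return I_x, I_y, b - a


@dataclass
class FlowWindow:
    """Gradient sums of one tracking window.

    C is the 2x2 structure tensor sum, D the gradient-temporal sum vector of
    the normal equations C (u, v)^T + D = 0.
    """

    center: tuple[float, float]
    half_width: int
    C: np.ndarray
    D: np.ndarray
    it_mean_abs: float = 0.0  # mean |I_t| over the window (residual diagnostic)


def _bilinear_window(px: np.ndarray, cx: float, cy: float, half: int) -> np.ndarray:
    """Sample a (2*half+1)^2 window centered at subpixel (cx, cy)."""
    offs = np.arange(-half, half + 1, dtype=float)
    xs = cx + offs
    ys = cy + offs
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    h, w = px.shape
    if x0.min() < 0 or y0.min() < 0 or x0.max() + 1 >= w or y0.max() + 1 >= h:
        raise InvalidInputError("window out of frame bounds")
    fy_c = fy[:, None]
    fx_c = fx[None, :]
    tl = px[np.ix_(y0, x0)]
    tr = px[np.ix_(y0, x0 + 1)]
    bl = px[np.ix_(y0 + 1, x0)]
    br = px[np.ix_(y0 + 1, x0 + 1)]
    return (
        tl * (1 - fy_c) * (1 - fx_c)
        + tr * (1 - fy_c) * fx_c
        + bl * fy_c * (1 - fx_c)
        + br * fy_c * fx_c
    )


def make_flow_window(
    frame_t,
    frame_t1,
    center: tuple[float, float],
    w: int = 3,
    guess: tuple[float, float] = (0.0, 0.0),
) -> FlowWindow:
    """Accumulate the window gradient sums around ``center``.

    The temporal difference is taken between frame_t's window at ``center``
    and frame_t1's window displaced by ``guess`` (bilinear subpixel sampling).
    """
    a = _as_pixels(frame_t)
    b = _as_pixels(frame_t1)
    cx, cy = center
    # sample one pixel wider so central differences cover the full window
    wa = _bilinear_window(a, cx, cy, w + 1)
    wb = _bilinear_window(b, cx + guess[0], cy + guess[1], w + 1)
    gy, gx = np.gradient(wa)
    Ix = gx[1:-1, 1:-1]
    Iy = gy[1:-1, 1:-1]
    It = (wb - wa)[1:-1, 1:-1]
    C = np.array(
        [[np.sum(Ix * Ix), np.sum(Ix * Iy)], [np.sum(Ix * Iy), np.sum(Iy * Iy)]]
    )
    D = np.array([np.sum(Ix * It), np.sum(Iy * It)])
    return FlowWindow(center=(cx, cy), half_width=w, C=C, D=D,
                      it_mean_abs=float(np.mean(np.abs(It))))


def min_eigenvalue(C: np.ndarray) -> float:
    """Smaller eigenvalue of a symmetric 2x2 matrix (closed form)."""
    tr = C[0, 0] + C[1, 1]
    det = C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
    disc = max(tr * tr / 4.0 - det, 0.0)
    return float(tr / 2.0 - np.sqrt(disc))


def solve_flow_window(win: FlowWindow, lam_min: float | None = None) -> np.ndarray | None:
    """Solve C (u, v)^T = -D; ``None`` signals a lost (textureless) feature.

    ``lam_min`` defaults to 1e-4 times the window area.
    """
    if lam_min is None:
        lam_min = 1e-4 * (2 * win.half_width + 1) ** 2
    if min_eigenvalue(win.C) < lam_min:
        return None
    return np.linalg.solve(win.C, -win.D)


@dataclass(frozen=True)
class TrackingConfig:
    """Tunable tracking parameters."""

    w: int = 3  # window half-width; window is (2w+1)^2
    j_max: int = 3  # deepest pyramid level
    lam_min_scale: float = 1e-4  # eigenvalue threshold per window pixel
    newton_tol: float = 0.01  # px, per-level iteration stop
    newton_max_iter: int = 20
    residual_max: float = 0.05  # mean |I_t| after solve marking loss

    @property
    def lam_min(self) -> float:
        return self.lam_min_scale * (2 * self.w + 1) ** 2


def pyramidal_flow(
    frame_t,
    frame_t1,
    point: tuple[float, float],
    j_max: int = 3,
    config: TrackingConfig | None = None,
    level_log: list | None = None,
) -> np.ndarray | None:
    """Coarse-to-fine displacement of ``point`` between two frames.

    At each level, starting from the deepest, the window displacement is
    iterated in Newton-Raphson fashion; the estimate is doubled when moving
    one level finer, and the returned displacement is sum_j 2^j d^j.
    Returns ``None`` when the feature is lost (insufficient texture at level 0).
    """
    cfg = config if config is not None else TrackingConfig(j_max=j_max)
    pa = build_pyramid(frame_t, cfg.j_max)
    pb = build_pyramid(frame_t1, cfg.j_max)
    x, y = float(point[0]), float(point[1])
    h, w_ = _as_pixels(frame_t).shape
    if not (0 <= x < w_ and 0 <= y < h):
        raise InvalidInputError(f"point {point} outside frame of shape {(h, w_)}")

    guess = np.zeros(2)  # running guess at the current level, in level pixels
    total = np.zeros(2)
    for j in range(cfg.j_max, -1, -1):
        a = pa.levels[j]
        b = pb.levels[j]
        cx, cy = x / 2**j, y / 2**j
        d_level = np.zeros(2)
        margin = cfg.w + 2
        lh, lw = a.shape
        feasible = (
            margin <= cx < lw - margin and margin <= cy < lh - margin
        )
        if feasible:
            for _ in range(cfg.newton_max_iter):
                try:
                    win = make_flow_window(a, b, (cx, cy), cfg.w,
                                           guess=tuple(guess + d_level))
                except InvalidInputError:
                    break
                incr = solve_flow_window(win, cfg.lam_min)
                if incr is None:
                    if j == 0:
                        return None  # textureless at full resolution: lost
                    break
                d_level = d_level + incr
                if float(np.linalg.norm(incr)) < cfg.newton_tol:
                    break
        if level_log is not None:
            level_log.append((j, d_level.copy()))
        total = total + (2**j) * d_level
        if j > 0:
            guess = 2.0 * (guess + d_level)
    return total


@dataclass
class FeatureTrack:
    """Per-feature trajectory with loss status."""

    feature_id: int
    positions: list[tuple[float, float]] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    status: str = "tracked"  # "tracked" | "lost"
    lost_at: int | None = None

    @property
    def is_live(self) -> bool:
        return self.status == "tracked"


def track_sequence(
    frames: list,
    initial: np.ndarray,
    config: TrackingConfig | None = None,
) -> list[FeatureTrack]:
    """Track N feature points across a frame sequence.

    Features failing the texture (eigenvalue) or residual criterion, or
    drifting out of bounds, are marked lost and hold no later positions.
    """
    if len(frames) < 2:
        raise InvalidInputError("need at least 2 frames to track")
    cfg = config or TrackingConfig()
    pixels = [_as_pixels(f) for f in frames]
    h, w_ = pixels[0].shape
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 2 or initial.shape[1] != 2:
        raise InvalidInputError("initial points must be (n, 2)")

    tracks = []
    for j, (x, y) in enumerate(initial, start=1):
        tr = FeatureTrack(feature_id=j)
        if 0 <= x < w_ and 0 <= y < h:
            tr.positions.append((float(x), float(y)))
            tr.residuals.append(0.0)
        else:
            tr.status, tr.lost_at = "lost", 0
        tracks.append(tr)

    for t in range(len(pixels) - 1):
        a, b = pixels[t], pixels[t + 1]
        for tr in tracks:
            if not tr.is_live:
                continue
            pos = np.array(tr.positions[-1])
            d = pyramidal_flow(a, b, tuple(pos), cfg.j_max, config=cfg)
            if d is None:
                tr.status, tr.lost_at = "lost", t + 1
                continue
            new_pos = pos + d
            m = cfg.w + 2
            if not (m <= new_pos[0] < w_ - m and m <= new_pos[1] < h - m):
                tr.status, tr.lost_at = "lost", t + 1
                continue
            try:
                win = make_flow_window(a, b, tuple(pos), cfg.w, guess=tuple(d))
                residual = win.it_mean_abs
            except InvalidInputError:
                tr.status, tr.lost_at = "lost", t + 1
                continue
            if residual > cfg.residual_max:
                tr.status, tr.lost_at = "lost", t + 1
                continue
            tr.positions.append((float(new_pos[0]), float(new_pos[1])))
            tr.residuals.append(residual)
    return tracks


# --- I/O ------------------------------------------------------------------

def load_frame(path, index: int = 0) -> Frame:
    """Load an 8- or 16-bit grayscale PNG/PGM, normalized to [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    scale = float(info.max) if info else 1.0
    return Frame(pixels=arr.astype(float) / scale, index=index)


def write_tracks_csv(path, tracks: list[FeatureTrack], header_comment: str = "") -> None:
    import pandas as pd

    rows = []
    for tr in tracks:
        for t, (x, y) in enumerate(tr.positions):
            rows.append(
                {"frame": t, "feature_id": tr.feature_id, "x": x, "y": y,
                 "status": "tracked", "residual": tr.residuals[t]}
            )
        if tr.status == "lost":
            rows.append(
                {"frame": tr.lost_at, "feature_id": tr.feature_id,
                 "x": np.nan, "y": np.nan, "status": "lost", "residual": np.nan}
            )
    df = pd.DataFrame(rows, columns=["frame", "feature_id", "x", "y", "status", "residual"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_tracks_csv(path) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.read_csv(path, comment="#")
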