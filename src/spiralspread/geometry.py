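"""Arena geometry: the folded double-spiral tunnel, projection of planar
points onto its skeleton, host layouts and linear distance metrics.

The experimental arena is a long narrow tunnel (centimetre-wide channel)
folded into two interleaved Archimedean spiral arms that meet at the centre,
so that several metres of tunnel fit inside a small rectangular plate.
Insects are released at the centre; every position along the tunnel is
described by a *signed arclength* ``s`` (cm) from the release point, negative
on the left arm and positive on the right arm.  All downstream statistics
operate on this linear coordinate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "SpiralSkeleton",
    "HostLayout",
    "LinearPoint",
    "build_spiral",
    "project_to_skeleton",
    "make_host_layout",
    "distance_metrics",
]


class GeometryError(ValueError):
    """Raised when a requested arena geometry is infeasible."""


@dataclass
class SpiralSkeleton:
    """Arclength-parameterised centerline of the folded tunnel.

    Attributes
    ----------
    polyline : (n, 2) array
        Ordered planar vertices in cm, running from the tip of the left arm,
        through the central release point, to the tip of the right arm.
    cumulative_arclength : (n,) array
        Arclength from the first vertex, computed from Euclidean segment
        lengths (strictly increasing).
    centre_index : int
        Index of the release-point vertex.
    total_length : float
        Total tunnel length in cm.
    bounding_box : (float, float)
        Width and height (cm) of the rectangle the arena must fit in.
    chirality : str
        ``"levogyrous"`` (left-turning) or ``"dextrogyrous"``.
    channel_width : float
        Width of the tunnel channel in cm.
    """

    polyline: np.ndarray
    cumulative_arclength: np.ndarray
    centre_index: int
    total_length: float
    bounding_box: tuple[float, float]
    chirality: str
    channel_width: float = 1.0

    @property
    def signed_arclength(self) -> np.ndarray:
        """Per-vertex signed arclength from the release point (cm)."""
        return self.cumulative_arclength - self.cumulative_arclength[self.centre_index]

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Planar point(s) at signed arclength ``s`` (linear interpolation)."""
        sa = self.signed_arclength
        x = np.interp(s, sa, self.polyline[:, 0])
        y = np.interp(s, sa, self.polyline[:, 1])
        return np.stack(np.broadcast_arrays(x, y), axis=-1)

    def to_json(self) -> str:
        """Serialise as JSON (polyline as ordered [x, y] cm pairs + metadata)."""
        return json.dumps(
            {
                "polyline": self.polyline.round(6).tolist(),
                "centre_index": int(self.centre_index),
                "total_length": float(self.total_length),
                "bounding_box": list(self.bounding_box),
                "chirality": self.chirality,
                "channel_width": float(self.channel_width),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SpiralSkeleton":
        d = json.loads(text)
        poly = np.asarray(d["polyline"], dtype=float)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        return cls(
            polyline=poly,
            cumulative_arclength=np.concatenate([[0.0], np.cumsum(seg)]),
            centre_index=int(d["centre_index"]),
            total_length=float(d["total_length"]),
            bounding_box=tuple(d["bounding_box"]),
            chirality=d["chirality"],
            channel_width=float(d["channel_width"]),
        )


@dataclass
class HostLayout:
    """Host-egg positions along the linear coordinate.

    ``positions`` are signed cm; ``patch_id`` groups co-located eggs (each egg
    is its own singleton patch in the diffuse modality, patches hold six eggs
    in the clumped modality).
    """

    positions: np.ndarray
    patch_id: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.patch_id = np.asarray(self.patch_id, dtype=int)

    @property
    def n_eggs(self) -> int:
        return self.positions.size

    @property
    def n_patches(self) -> int:
        return np.unique(self.patch_id).size if self.positions.size else 0


@dataclass
class LinearPoint:
    """A planar detection expressed in tunnel coordinates: signed arclength
    ``s`` from the release point (negative = left arm) and perpendicular
    ``offset`` to the skeleton (cm)."""

    s: float
    offset: float


def _archimedean_arm(arm_length: float, b: float, resolution: float) -> np.ndarray:
    """Vertices of one Archimedean arm r = b*theta with total arclength
    ``arm_length``, resampled at ~uniform arclength steps <= resolution."""

    def arclen(theta: float) -> float:
        # closed form for integral of sqrt(r^2 + (dr/dtheta)^2) with r = b*theta
        return 0.5 * b * (theta * np.hypot(1.0, theta) + np.arcsinh(theta))

    theta_max = brentq(lambda th: arclen(th) - arm_length, 0.0, 1e4)
    # dense theta grid, then invert the arclength map onto a uniform s grid
    theta_dense = np.linspace(0.0, theta_max, max(2000, int(20 * arm_length)))
    s_dense = 0.5 * b * (theta_dense * np.hypot(1.0, theta_dense) + np.arcsinh(theta_dense))
    n_pts = int(np.ceil(arm_length / resolution)) + 1
    s_grid = np.linspace(0.0, arm_length, n_pts)
    theta = np.interp(s_grid, s_dense, theta_dense)
    r = b * theta
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def build_spiral(
    total_length: float = 630.0,
    box: tuple[float, float] = (60.0, 40.0),
    channel_width: float = 1.0,
    chirality: str = "levogyrous",
    wall_thickness: float = 0.3,
    resolution: float = 0.1,
) -> SpiralSkeleton:
    """Construct the double-spiral skeleton.

    The tunnel is modelled as two interleaved Archimedean spiral arms meeting
    smoothly at the centre (the second arm is the first rotated by 180°), with
    radial pitch ``2 * (channel_width + wall_thickness)`` so the two channels
    interleave without overlapping.

    Parameters
    ----------
    total_length : float
        Target tunnel arclength (cm); each arm carries half of it.
    box : (float, float)
        Rectangle (width, height) in cm the arena must fit into.
    channel_width, wall_thickness : float
        Channel width and separating wall thickness (cm); they set the pitch.
    chirality : str
        ``"levogyrous"`` (counter-clockwise outward) or ``"dextrogyrous"``
        (its mirror image).
    resolution : float
        Approximate arclength spacing of the returned polyline (cm).

    Raises
    ------
    GeometryError
        If the spiral of the requested length cannot fit inside ``box`` at
        the given pitch.
    """
    if total_length <= 0:
        raise GeometryError("total_length must be positive")
    if chirality not in ("levogyrous", "dextrogyrous"):
        raise GeometryError(f"unknown chirality: {chirality!r}")

    pitch = 2.0 * (channel_width + wall_thickness)
    b = pitch / (2.0 * np.pi)
    arm = _archimedean_arm(total_length / 2.0, b, resolution)

    r_outer = np.max(np.hypot(arm[:, 0], arm[:, 1])) + channel_width / 2.0
    if 2.0 * r_outer > min(box):
        raise GeometryError(
            f"spiral of length {total_length} cm at pitch {pitch} cm has outer "
            f"diameter {2 * r_outer:.1f} cm and cannot fit a {box[0]}x{box[1]} cm box"
        )

    if chirality == "dextrogyrous":
        arm = arm * np.array([1.0, -1.0])  # mirror image

    left = -arm[::-1]  # second arm: rotation by pi, ordered tip -> centre
    polyline = np.vstack([left[:-1], arm])
    centre_index = left.shape[0] - 1
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return SpiralSkeleton(
        polyline=polyline,
        cumulative_arclength=cum,
        centre_index=centre_index,
        total_length=float(cum[-1]),
        bounding_box=tuple(box),
        chirality=chirality,
        channel_width=channel_width,
    )


def project_to_skeleton(skeleton: SpiralSkeleton, xy) -> LinearPoint:
    """Project a planar point orthogonally onto the skeleton.

    Returns the signed arclength of the nearest skeleton point and the
    perpendicular offset.  Ties between the two arms are broken by the smaller
    offset, then by the smaller ``|s|``.  A warning is emitted when the offset
    exceeds half the channel width (the point lies outside the tunnel).
    """
    p = np.asarray(xy, dtype=float)
    a = skeleton.polyline[:-1]
    d = np.diff(skeleton.polyline, axis=0)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    # parameter of the orthogonal projection onto each segment, clamped
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / np.maximum(seg_len2, 1e-300), 0.0, 1.0)
    foot = a + t[:, None] * d
    dist = np.hypot(*(p - foot).T)
    s_all = (
        skeleton.cumulative_arclength[:-1]
        + t * np.sqrt(seg_len2)
        - skeleton.cumulative_arclength[skeleton.centre_index]
    )
    # nearest segment; break near-ties by smaller |s|
    dmin = dist.min()
    close = np.flatnonzero(dist <= dmin + 1e-9)
    best = close[np.argmin(np.abs(s_all[close]))]
    offset = float(dist[best])
    if offset > skeleton.channel_width / 2.0 + 0.05:
        warnings.warn(
            f"point {tuple(p)} lies {offset:.2f} cm from the skeleton, outside "
            f"the {skeleton.channel_width:.2f} cm channel",
            stacklevel=2,
        )
    return LinearPoint(s=float(s_all[best]), offset=offset)


def make_host_layout(
    modality: str,
    tunnel_half_length: float = 315.0,
    cutoff: float = 300.0,
) -> HostLayout:
    """Generate a host-egg layout along the linear coordinate.

    Diffuse: one egg every 5 cm, the first 2.5 cm on each side of the centre
    (singleton patches).  Clumped: one patch of six co-located eggs every
    30 cm, the first 15 cm on each side.  Eggs are placed out to ``cutoff``
    cm from the centre; with the default 300 cm cutoff both modalities hold
    exactly 120 eggs, i.e. the same mean host density.
    """
    if modality == "none":
        return HostLayout(np.empty(0), np.empty(0, dtype=int), "none")
    if cutoff > tunnel_half_length:
        raise GeometryError("cutoff exceeds tunnel half-length")
    if modality == "diffuse":
        right = np.arange(2.5, cutoff + 1e-9, 5.0)
        pos = np.concatenate([-right[::-1], right])
        return HostLayout(pos, np.arange(pos.size), "diffuse")
    if modality == "clumped":
        right = np.arange(15.0, cutoff + 1e-9, 30.0)
        centres = np.concatenate([-right[::-1], right])
        pos = np.repeat(centres, 6)
        patch = np.repeat(np.arange(centres.size), 6)
        return HostLayout(pos, patch, "clumped")
    raise GeometryError(f"unknown host layout modality: {modality!r}")


def distance_metrics(positions, layout: HostLayout | None = None):
    """Nearest-host distance per individual and all pairwise distances.

    Distances are measured along the linear tunnel coordinate.  When the
    layout is empty the nearest-host distance is ``inf``.

    Returns
    -------
    nearest_host : (n,) array
    pairwise : (n, n) array
    """
    x = np.asarray(positions, dtype=float)
    pairwise = np.abs(x[:, None] - x[None, :])
    if layout is None or layout.n_eggs == 0:
        nearest = np.full(x.shape, np.inf)
    else:
        nearest = np.abs(x[:, None] - layout.positions[None, :]).min(axis=1)
    return nearest, pairwise
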