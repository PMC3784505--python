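"""Physical plane model: head and whisker geometry in a 2-D world.

The head is a rigid rod from the neck joint to the snout tip (the *fovea*);
its bearing is the neck-to-fovea direction.  Fourteen whiskers (seven per
side) are constant-curvature arcs rooted on the mystacial pad arcs of the
snout outline.  Bending against oriented rectangular obstacles is resolved
quasistatically: the curvature of an intersecting whisker is adjusted
increasingly caudally until the shaft just clears every obstacle, and the
resulting shaft deviation near the base yields a saturating afferent contact
signal.

Angle convention
----------------
A whisker's protraction (base) angle is measured from the caudal direction of
the head midline and increases rostrally: 0 deg points straight back, 90 deg
points laterally (to the whisker's own side), and angles approaching 180 deg
point straight ahead.  Positive rest curvature bends the shaft rostrally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .params import ObstacleSpec, Params

__all__ = [
    "HeadPose", "WhiskerMorph", "BendResult", "FrameTransform",
    "build_morphology", "arc_polyline", "resolve_bending", "bend_all",
    "step_neck", "pack_obstacles",
]

# pad-arc geometry (head frame): the snout outline is an ellipse whose
# rostral tip sits at the fovea; whisker bases are spread along it
_SNOUT_SEMI_LONG = 30.0   # mm, longitudinal semi-axis
_SNOUT_SEMI_LAT = 12.0    # mm, lateral semi-axis
_PAD_T_ROSTRAL = 15.0     # deg of ellipse parameter from the tip
_PAD_T_CAUDAL = 75.0

_BEND_DK_MAX = 0.25       # 1/mm, upper bound on the caudal curvature offset
_BEND_DK_TOL = 1e-4       # 1/mm, bisection tolerance
_BEND_ARC_STEP = 1.0      # mm, shaft discretization for intersection tests


@dataclass(frozen=True)
class HeadPose:
    """Fovea and neck positions in the world frame (mm)."""

    fovea: np.ndarray
    neck: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "fovea", np.asarray(self.fovea, float))
        object.__setattr__(self, "neck", np.asarray(self.neck, float))

    @property
    def bearing(self) -> float:
        """Head bearing in radians: direction from the neck to the fovea."""
        d = self.fovea - self.neck
        return float(np.arctan2(d[1], d[0]))

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.fovea - self.neck))

    def check(self, sep: float, tol: float = 1e-6) -> None:
        if abs(self.separation - sep) > tol:
            raise ValueError(
                f"fovea-neck separation {self.separation:.9f} != {sep} mm")


@dataclass(frozen=True)
class WhiskerMorph:
    """Static morphology of one whisker (head frame)."""

    side: str                 # "left" | "right"
    index: int                # 1 = most caudal .. n = most rostral
    base_point: np.ndarray    # mm, head frame
    base_tangent: float       # deg, local pad-arc tangent heading
    length: float             # mm
    rest_curvature: float     # 1/mm, positive = rostral bend


@dataclass(frozen=True)
class BendResult:
    """Outcome of the quasistatic bending solve for one whisker."""

    perturbed_curvature: float
    deviation: float              # mm, at the deformation-measurement point
    contact_signal: float         # in [0, 1]
    contact_point: np.ndarray | None   # world frame, or None if no contact
    clamped: bool = False         # True if the solver hit its curvature bound


class FrameTransform:
    """Bidirectional map between world and head coordinates.

    Head frame: origin at the fovea, +x along the bearing, +y to the
    animal's left.
    """

    def __init__(self, pose: HeadPose):
        self.pose = pose
        b = pose.bearing
        self._c = np.cos(b)
        self._s = np.sin(b)

    def world_from_head(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        x, y = p[..., 0], p[..., 1]
        out = np.empty(np.shape(p), float)
        out[..., 0] = self.pose.fovea[0] + self._c * x - self._s * y
        out[..., 1] = self.pose.fovea[1] + self._s * x + self._c * y
        return out

    def head_from_world(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        dx = p[..., 0] - self.pose.fovea[0]
        dy = p[..., 1] - self.pose.fovea[1]
        out = np.empty(np.shape(p), float)
        out[..., 0] = self._c * dx + self._s * dy
        out[..., 1] = -self._s * dx + self._c * dy
        return out


def build_morphology(params: Params) -> list[WhiskerMorph]:
    """Lay out the whisker array on the mystacial pad arcs.

    Returns 14 whiskers, left side first, each side ordered caudal to
    rostral; the two sides are mirror images about the head midline.
    """
    n = params.n_whiskers_per_side
    lengths = params.whisker_lengths
    curvatures = params.whisker_curvatures
    # ellipse parameter: most caudal base farthest from the tip
    ts = np.deg2rad(np.linspace(_PAD_T_CAUDAL, _PAD_T_ROSTRAL, n))
    morphs: list[WhiskerMorph] = []
    for side_name, sgn in (("left", 1.0), ("right", -1.0)):
        for i in range(n):
            t = ts[i]
            base = np.array([
                -_SNOUT_SEMI_LONG + _SNOUT_SEMI_LONG * np.cos(t),
                sgn * _SNOUT_SEMI_LAT * np.sin(t),
            ])
            tangent = np.rad2deg(np.arctan2(sgn * _SNOUT_SEMI_LAT * np.cos(t),
                                            -_SNOUT_SEMI_LONG * np.sin(t)))
            morphs.append(WhiskerMorph(
                side=side_name, index=i + 1, base_point=base,
                base_tangent=float(tangent), length=float(lengths[i]),
                rest_curvature=float(curvatures[i])))
    return morphs


def _heading(base_angle_deg: float, side_sign: float) -> float:
    """Initial shaft heading (standard math angle, rad) in the head frame."""
    th = np.deg2rad(base_angle_deg)
    return np.pi - th if side_sign > 0 else th - np.pi


def arc_polyline(morph: WhiskerMorph, base_angle: float, curvature: float,
                 step: float = _BEND_ARC_STEP) -> np.ndarray:
    """Vertices of the whisker arc in the head frame, spacing <= ``step``."""
    if step <= 0:
        raise ValueError("step must be > 0")
    sgn = 1.0 if morph.side == "left" else -1.0
    alpha0 = _heading(base_angle, sgn)
    kap_eff = -sgn * curvature
    n = int(np.ceil(morph.length / step)) + 1
    s = np.linspace(0.0, morph.length, n)
    if abs(kap_eff) < 1e-12:
        xs = morph.base_point[0] + s * np.cos(alpha0)
        ys = morph.base_point[1] + s * np.sin(alpha0)
    else:
        a = alpha0 + kap_eff * s
        xs = morph.base_point[0] + (np.sin(a) - np.sin(alpha0)) / kap_eff
        ys = morph.base_point[1] + (np.cos(alpha0) - np.cos(a)) / kap_eff
    return np.column_stack([xs, ys])


def pack_obstacles(obstacles: Sequence[ObstacleSpec]) -> np.ndarray:
    """Pack obstacle specs into the (n, 6) array the kernels consume."""
    arr = np.empty((len(obstacles), 6), float)
    for j, ob in enumerate(obstacles):
        a = np.deg2rad(ob.angle_deg)
        arr[j] = (ob.cx_mm, ob.cy_mm, ob.width_mm / 2.0, ob.height_mm / 2.0,
                  np.cos(a), np.sin(a))
    return arr


class _MorphArrays:
    """Morphology flattened to the arrays the bending kernel consumes."""

    def __init__(self, morphs: Sequence[WhiskerMorph]):
        self.base_head = np.array([m.base_point for m in morphs])
        self.side = np.array([1.0 if m.side == "left" else -1.0 for m in morphs])
        self.kappa = np.array([m.rest_curvature for m in morphs])
        self.length = np.array([m.length for m in morphs])


def bend_all(morphs: Sequence[WhiskerMorph] | _MorphArrays,
             theta_base: np.ndarray, pose: HeadPose,
             obstacles: np.ndarray, params: Params,
             gains: np.ndarray | None = None):
    """Resolve bending for every whisker at once (fast path).

    Returns ``(perturbed_curvature, deviation, contact_signal, contact_point,
    clamped)`` arrays; contact points are NaN where there is no contact.
    """
    ma = morphs if isinstance(morphs, _MorphArrays) else _MorphArrays(morphs)
    nw = ma.side.shape[0]
    if gains is None:
        gains = params.sensing_gain_scale * np.sqrt(ma.length)
    b = pose.bearing
    kout = np.empty(nw)
    dout = np.empty(nw)
    cout = np.empty(nw)
    pout = np.empty((nw, 2))
    clout = np.zeros(nw, bool)
    _kernels.bend_whiskers(
        np.asarray(theta_base, float), ma.base_head, ma.side, ma.kappa,
        ma.length, np.asarray(gains, float),
        pose.fovea, np.cos(b), np.sin(b), obstacles,
        params.deformation_dist, _BEND_ARC_STEP, _BEND_DK_MAX, _BEND_DK_TOL,
        kout, dout, cout, pout, clout)
    return kout, dout, cout, pout, clout


def resolve_bending(morph: WhiskerMorph, base_angle: float, pose: HeadPose,
                    obstacles: Sequence[ObstacleSpec] | np.ndarray,
                    params: Params) -> BendResult:
    """Resolve quasistatic bending for a single whisker."""
    obs = obstacles if isinstance(obstacles, np.ndarray) else pack_obstacles(obstacles)
    i = morph.index - 1
    gain = params.sensing_gains[i] if i < params.n_whiskers_per_side else \
        params.sensing_gain_scale * np.sqrt(morph.length)
    k, d, c, p, cl = bend_all(
        _MorphArrays([morph]), np.array([base_angle]), pose, obs, params,
        gains=np.array([gain]))
    contact_point = None if not c[0] > 0.0 else p[0].copy()
    return BendResult(perturbed_curvature=float(k[0]), deviation=float(d[0]),
                      contact_signal=float(c[0]), contact_point=contact_point,
                      clamped=bool(cl[0]))


def step_neck(pose: HeadPose, new_fovea: np.ndarray, sep: float) -> HeadPose:
    """Drag the neck along the line toward the new fovea, keeping separation."""
    new_fovea = np.asarray(new_fovea, float)
    d = pose.neck - new_fovea
    dist = np.linalg.norm(d)
    if dist < 1e-12:
        raise ValueError("new fovea position coincides with the neck joint")
    neck = new_fovea + d * (sep / dist)
    return HeadPose(fovea=new_fovea, neck=neck)
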