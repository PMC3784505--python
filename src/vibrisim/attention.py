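"""Salience-map attention: excitation, inhibition and channel selection.

Two head-centric scalar fields — a *tactile* channel fed by whisker contacts
and an *other* channel fed by an endogenous stochastic source — compete for
attention.  Each excitation map keeps a memory of past input through a
leaky-max update whose spatial validity under head movement is preserved by a
dynamic remapping (an affine image warp that compensates the pose change
between samples).  Inhibition combines an absolute component inside and
behind obstacles with a capped inhibition-of-return (IOR) component over
recently foveated locations; salience is excitation gated by inhibition, and
the channel with the higher salience peak is selected at each oscillator
tick.

All fields live on a fixed grid in the head frame: x in [-40, +40] mm
around the fovea (positive ahead), y in [-60, +60] mm (positive to the
animal's left), with square cells of side ``grid_resolution``.  The
whiskers' reach spans only the rostral part of this area, so the symmetric
longitudinal extent mainly serves the endogenous channel: candidate
attention targets can fall beside and behind the head even when the space
ahead is occluded by an obstacle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import _kernels
from .params import Params
from .plane import FrameTransform, HeadPose

__all__ = [
    "GridSpec", "NoiseState", "IORMemory",
    "deposit_blobs", "remap_field", "update_excitation", "other_input",
    "obstacle_inhibition", "ior_step", "ior_field", "inhibition", "salience",
    "select_channel",
]

_X_BEHIND = 40.0   # mm of grid behind the fovea
_X_AHEAD = 40.0    # mm of grid ahead of the fovea
_Y_HALF = 60.0     # mm of grid to each side


class GridSpec:
    """Geometry of the head-centric field grid."""

    def __init__(self, params: Params):
        self.cell = float(params.grid_resolution)
        self.x0 = -_X_BEHIND
        self.y0 = -_Y_HALF
        self.nx = int(round((_X_BEHIND + _X_AHEAD) / self.cell))
        self.ny = int(round(2 * _Y_HALF / self.cell))
        xs = self.x0 + self.cell * (np.arange(self.nx) + 0.5)
        ys = self.y0 + self.cell * (np.arange(self.ny) + 0.5)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        #: (nx*ny, 2) cell-center coordinates in the head frame, C order
        self.centers = np.column_stack([gx.ravel(), gy.ravel()])
        self.xs = xs
        self.ys = ys

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def cell_center(self, ix: int, iy: int) -> np.ndarray:
        return np.array([self.x0 + self.cell * (ix + 0.5),
                         self.y0 + self.cell * (iy + 0.5)])

    def contains(self, p: np.ndarray) -> bool:
        return (self.x0 <= p[0] <= self.x0 + self.nx * self.cell
                and self.y0 <= p[1] <= self.y0 + self.ny * self.cell)


def deposit_blobs(spec: GridSpec, values: np.ndarray, points: np.ndarray,
                  amplitudes: np.ndarray, width: float) -> np.ndarray:
    """Add Gaussian blobs at head-frame ``points`` and clip the result to 1.

    ``width`` is the blob's nominal diameter, interpreted as two standard
    deviations.  Points outside the grid extent are silently ignored.
    """
    if width <= 0:
        raise ValueError("blob width must be > 0")
    out = values.copy()
    points = np.atleast_2d(np.asarray(points, float))
    if points.size:
        _kernels.deposit_gaussians(out, points,
                                   np.asarray(amplitudes, float).ravel(),
                                   width / 2.0, spec.x0, spec.y0, spec.cell)
    np.clip(out, None, 1.0, out=out)
    return out


_REMAP_BLUR_MM = 1.0   # reconstruction-filter width of the lossy warp


def remap_field(spec: GridSpec, values: np.ndarray, pose_old: HeadPose,
                pose_new: HeadPose) -> np.ndarray:
    """Warp a field so its content stays fixed in the world frame.

    The value at head-frame location x in the output estimates the value at
    the same *world* location in the input (bilinear interpolation; regions
    whose pre-image falls outside the old grid become 0).  Re-sampling onto
    the discrete grid uses a Gaussian reconstruction filter of width
    ``_REMAP_BLUR_MM``, which makes the warp deliberately lossy: memory that
    is not refreshed diffuses and fades within a few whisks, which is what
    bounds the excitation maps' effective memory (no explicit decay factor
    is applied).  Identical poses return the field unchanged.
    """
    db = pose_new.bearing - pose_old.bearing
    if db == 0.0 and np.array_equal(pose_new.fovea, pose_old.fovea):
        return values.copy()
    c, s = np.cos(db), np.sin(db)
    R = np.array([[c, -s], [s, c]])
    bo = pose_old.bearing
    co, so = np.cos(bo), np.sin(bo)
    Rm = np.array([[co, so], [-so, co]])        # rotation by -bearing_old
    t = Rm @ (pose_new.fovea - pose_old.fovea)
    o = np.array([spec.x0, spec.y0]) + 0.5 * spec.cell
    offset = (R @ o + t - o) / spec.cell
    out = ndimage.affine_transform(values, R, offset=offset, order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    ndimage.gaussian_filter(out, _REMAP_BLUR_MM / spec.cell, output=out,
                            mode="constant", cval=0.0)
    return out


@dataclass
class NoiseState:
    """Per-cell first-order (AR(1)) coloured-noise state for one channel.

    The autoregressive coefficient is ``exp(-2*pi*bandwidth*dt)`` and the
    innovation is scaled so the stationary per-cell variance is one.
    """

    state: np.ndarray
    coeff: float
    innov_scale: float

    @classmethod
    def create(cls, spec: GridSpec, params: Params) -> "NoiseState":
        a = float(np.exp(-2.0 * np.pi * params.noise_bandwidth * params.sample_dt))
        return cls(state=spec.zeros(), coeff=a,
                   innov_scale=float(np.sqrt(1.0 - a * a)))

    def step(self, rng: np.random.Generator, mirror: bool = False) -> np.ndarray:
        """Advance one sample and return the unit-variance noise field."""
        eps = rng.standard_normal(self.state.shape)
        self.state *= self.coeff
        self.state += self.innov_scale * eps
        return self.state[:, ::-1] if mirror else self.state


def update_excitation(spec: GridSpec, E: np.ndarray, I: np.ndarray,
                      pose_old: HeadPose, pose_new: HeadPose,
                      noise_field: np.ndarray, gain: float,
                      keep_memory: bool = True) -> np.ndarray:
    """Leaky-max excitation update with remapping, noise and clipping.

    ``E' = clip(max(remap(E), I, gain * noise), 0, 1)``, the maximum taken
    entry-wise over the three operands.  Because the noise enters through
    the maximum it perturbs the map without accumulating over samples; the
    decay of the leaky-max memory is provided implicitly by the lossy warp,
    so no explicit decay factor is applied.  With ``keep_memory=False`` the
    remapped history is discarded and the map is rebuilt from the input and
    noise alone (used to hold the endogenous channel to a single active
    region when a new target is generated).
    """
    if keep_memory:
        out = remap_field(spec, E, pose_old, pose_new)
        np.maximum(out, I, out=out)
    else:
        out = I.copy()
    if gain != 0.0:
        np.maximum(out, gain * noise_field, out=out)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def other_input(spec: GridSpec, tick: bool, rng: np.random.Generator,
                params: Params, mirror: bool = False,
                allowed: np.ndarray | None = None) -> np.ndarray:
    """Endogenous input: one random blob per oscillator tick, else empty.

    The blob center is sampled uniformly over the grid extent (head frame).
    If ``allowed`` (a boolean field over the grid) is given, locations where
    it is False — cells inside or occluded by obstacles — are rejected and
    redrawn: the endogenous source stands in for motivational and
    non-tactile sensory systems, which propose attainable targets.
    """
    out = spec.zeros()
    if tick:
        x = y = 0.0
        for _ in range(200):
            x = rng.uniform(spec.x0, spec.x0 + spec.nx * spec.cell)
            y = rng.uniform(spec.y0, spec.y0 + spec.ny * spec.cell)
            if mirror:
                y = -y
            if allowed is None:
                break
            ix = min(int((x - spec.x0) / spec.cell), spec.nx - 1)
            iy = min(int((y - spec.y0) / spec.cell), spec.ny - 1)
            if allowed[ix, iy]:
                break
        _kernels.deposit_gaussians(out, np.array([[x, y]]),
                                   np.array([params.other_gain]),
                                   params.other_blob_width / 2.0,
                                   spec.x0, spec.y0, spec.cell)
        np.clip(out, None, 1.0, out=out)
    return out


def obstacle_inhibition(spec: GridSpec, obstacles: np.ndarray,
                        pose: HeadPose) -> np.ndarray:
    """Unity inhibition inside and behind obstacles (fovea's viewpoint)."""
    if obstacles.shape[0] == 0:
        return spec.zeros()
    tf = FrameTransform(pose)
    cells_world = tf.world_from_head(spec.centers)
    out = np.empty(spec.nx * spec.ny)
    _kernels.obstacle_shadow(cells_world, pose.fovea, obstacles, out)
    return out.reshape(spec.shape)


@dataclass
class IORMemory:
    """Allocentric set of recently foveated locations with timestamps."""

    points: list = field(default_factory=list)     # world points (np arrays)
    times: list = field(default_factory=list)      # s


def ior_step(mem: IORMemory, fovea: np.ndarray, t: float,
             params: Params) -> IORMemory:
    """Add the current fovea location and expire entries older than memory."""
    points = [p for p, ts in zip(mem.points, mem.times)
              if t - ts <= params.ior_memory]
    times = [ts for ts in mem.times if t - ts <= params.ior_memory]
    points.append(np.asarray(fovea, float).copy())
    times.append(float(t))
    return IORMemory(points=points, times=times)


def ior_field(spec: GridSpec, mem: IORMemory, pose: HeadPose,
              params: Params) -> np.ndarray:
    """Additive Gaussian inhibition blobs at the visited locations."""
    out = spec.zeros()
    if not mem.points:
        return out
    tf = FrameTransform(pose)
    centers = tf.head_from_world(np.array(mem.points))
    amps = np.full(len(mem.points), params.ior_gain)
    _kernels.deposit_gaussians(out, centers, amps, params.ior_width / 2.0,
                               spec.x0, spec.y0, spec.cell)
    return out


def inhibition(H_obs: np.ndarray, H_ior: np.ndarray, params: Params) -> np.ndarray:
    """Combine obstacle and (capped) IOR inhibition: min(1, H_obs + min(H_ior, cap))."""
    return np.minimum(1.0, H_obs + np.minimum(H_ior, params.ior_max))


def salience(E: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Salience is excitation gated by inhibition: S = E * (1 - H)."""
    return E * (1.0 - H)


def select_channel(S_tactile: np.ndarray, S_other: np.ndarray,
                   previous: str = "other") -> str:
    """Pick the channel with the higher salience peak; ties keep ``previous``."""
    mt = float(S_tactile.max())
    mo = float(S_other.max())
    if mt > mo:
        return "tactile"
    if mo > mt:
        return "other"
    return previous
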