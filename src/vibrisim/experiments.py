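"""Simulated behavioural experiments and their analyses.

Three classic observations of rat active whisker sensing are reproduced with
the exact analysis pipelines used on the behavioural video data:

* **HTA** (head-turning asymmetry): in free space, the left-minus-right
  difference of the bilateral mean protraction angles is regressed on the
  smoothed head-bearing turn rate.
* **CIA** (contact-induced asymmetry): during an hour of arena exploration,
  mean protraction relative to a far-from-walls baseline is mapped against
  the position of a single nearby wall.
* **SR** (spread reduction): during straight-line approaches to a wall, the
  angular spread between a caudal and a rostral whisker is compared across
  the pre-contact, first-contact and second-contact whisks.

The *measured* protraction angle follows the behavioural-lab convention: the
angle between the head midline and the chord from the whisker base to the
point two thirds of the way along the (possibly bent) shaft.  Whisker base
angles are carried alongside as the bending-free control measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from . import engine
from .engine import SimLog
from .params import ObstacleSpec, Params
from .plane import HeadPose, WhiskerMorph, arc_polyline

__all__ = [
    "HTAResult", "CIAResult", "SRResult", "WhiskInterval",
    "measured_angle", "segment_whisks", "turn_rate", "zero_phase_lowpass",
    "run_hta", "run_cia", "run_sr", "make_arena", "calibrate_sensing_gain",
]

_FILTER_CUTOFF_HZ = 2.0
_NEAR_DIST = 25.0     # mm: nose-to-wall distance bounding the NEAR set
_FAR_DIST = 100.0     # mm: minimum distance to every wall for FAR
_CIA_BIN = 4.0        # mm: square bin size of the CIA map
_CIA_HALF = 28.0      # mm: half-extent of the binned wall-point map
_SR_START_DIST = 50.0  # mm: nose-to-wall distance at trial start
_SR_STOP_DIST = 5.0    # mm: nose-to-wall distance ending a trial
_SPREAD_CAUDAL = 1     # rearmost whisker of the spread pair
_SPREAD_ROSTRAL = 5    # fifth-from-rear whisker of the spread pair


# ---------------------------------------------------------------------------
# measurement primitives

def measured_angle(morph: WhiskerMorph, base_angle: float,
                   curvature: float) -> float:
    """Behavioural-convention protraction angle of one whisker shaft.

    Angle (deg) between the head midline and the chord from the base to the
    point two thirds along the shaft at the given (possibly perturbed)
    curvature, in the base-angle convention (0 = caudal, increasing
    rostrally).
    """
    poly = arc_polyline(morph, base_angle, curvature, step=morph.length / 300.0)
    k = int(round(2 / 3 * (len(poly) - 1)))
    v = poly[k] - morph.base_point
    beta = np.degrees(np.arctan2(v[1], v[0]))
    theta = 180.0 - beta if morph.side == "left" else beta + 180.0
    return float(theta % 360.0)


def zero_phase_lowpass(x: np.ndarray, fs: float,
                       cutoff: float = _FILTER_CUTOFF_HZ) -> np.ndarray:
    """Forward-backward second-order Butterworth low-pass."""
    sos = signal.butter(2, cutoff, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def turn_rate(bearing_deg: np.ndarray, dt: float,
              smooth: bool = True) -> np.ndarray:
    """Head turn rate in degrees per millisecond.

    Central difference of the unwrapped bearing, optionally smoothed with the
    same zero-phase 2 Hz low-pass used throughout the analyses.
    """
    b = np.unwrap(bearing_deg, period=360.0)
    rate = np.gradient(b, dt) / 1000.0     # deg/s -> deg/ms
    if smooth:
        rate = zero_phase_lowpass(rate, fs=1.0 / dt)
    return rate


@dataclass(frozen=True)
class WhiskInterval:
    """One whisk: the samples between consecutive oscillator ticks."""

    start: int      # first sample index (exclusive of the previous tick)
    end: int        # last sample index (the tick sample: maximum protraction)
    index: int      # whisk ordinal within the log (0-based)
    has_contact: bool
    n_whiskers_contacting: int
    label: str = ""   # "", "pre", "first", "second"


def segment_whisks(log: SimLog, side: str) -> list[WhiskInterval]:
    """Split a log into whisks and classify contact whisks for one side.

    A whisk spans the samples after one tick up to and including the next
    (maximum protraction falls on the tick sample).  A contact whisk has at
    least one sample with a positive contact signal on the given side; the
    first two contact whisks are labelled ``first`` and ``second`` and the
    whisk immediately before the first is labelled ``pre``.
    """
    ticks = np.flatnonzero(log.df["tick"].to_numpy() > 0)
    contacts = log.whisker_matrix("contact", side)
    intervals: list[WhiskInterval] = []
    for k in range(1, len(ticks)):
        s, e = ticks[k - 1] + 1, ticks[k]
        c = contacts[s:e + 1]
        n_contacting = int(np.count_nonzero((c > 0.0).any(axis=0)))
        intervals.append(WhiskInterval(
            start=int(s), end=int(e), index=k - 1,
            has_contact=n_contacting > 0,
            n_whiskers_contacting=n_contacting))
    contact_ids = [w.index for w in intervals if w.has_contact]
    labels: dict[int, str] = {}
    if contact_ids:
        labels[contact_ids[0]] = "first"
        if len(contact_ids) > 1:
            labels[contact_ids[1]] = "second"
        if contact_ids[0] > 0:
            labels[contact_ids[0] - 1] = "pre"
    return [WhiskInterval(w.start, w.end, w.index, w.has_contact,
                          w.n_whiskers_contacting, labels.get(w.index, ""))
            for w in intervals]


def calibrate_sensing_gain(params: Params, seed: int = 0,
                           duration: float = 60.0,
                           target_band: tuple[float, float] = (0.5, 0.8)
                           ) -> float:
    """Calibrate the sensing-gain scale so contact signals use their range.

    The per-whisker gain is ``k_g * sqrt(length)``; this searches a log grid
    of ``k_g`` values, running a short arena exploration for each, and
    returns the value whose median nonzero contact signal lies closest to
    the middle of ``target_band`` (the gains should roughly normalise the
    contact-signal strength across whiskers without saturating them).
    """
    walls = make_arena()
    lo, hi = target_band
    mid = 0.5 * (lo + hi)
    best_kg, best_err = params.sensing_gain_scale, np.inf
    for kg in np.logspace(-2, 1, 16):
        p = params.replace(sensing_gain_scale=float(kg))
        log = engine.run(p, obstacles=walls, duration=duration, seed=seed)
        c = np.concatenate([log.whisker_matrix("contact", s).ravel()
                            for s in ("L", "R")])
        nz = c[c > 0.0]
        if len(nz) == 0:
            continue
        med = float(np.median(nz))
        err = abs(med - mid)
        if err < best_err:
            best_err, best_kg = err, float(kg)
    return best_kg


# ---------------------------------------------------------------------------
# head-turning asymmetry

@dataclass
class HTAResult:
    """OLS fit of protraction asymmetry against head turn rate."""

    slope: float          # deg per (deg/ms)
    intercept: float      # deg
    correlation: float    # Pearson r
    n: int
    pairs: np.ndarray     # (n, 2): turn rate, asymmetry
    log: SimLog | None = None


def analyze_hta(log: SimLog) -> HTAResult:
    dt = float(log.meta["params"]["sample_dt"])
    mean_l = log.whisker_matrix("theta_meas", "L").mean(axis=1)
    mean_r = log.whisker_matrix("theta_meas", "R").mean(axis=1)
    asym = mean_l - mean_r
    rate = turn_rate(log.df["bearing_deg"].to_numpy(), dt)
    if np.std(rate) < 1e-12:
        raise ValueError("degenerate head-turn-rate series (zero variance)")
    fit = stats.linregress(rate, asym)
    return HTAResult(slope=float(fit.slope), intercept=float(fit.intercept),
                     correlation=float(fit.rvalue), n=len(asym),
                     pairs=np.column_stack([rate, asym]), log=log)


def run_hta(params: Params, seed: int = 0, duration: float = 30.0) -> HTAResult:
    """Free-space run: attention driven only by the stochastic channel."""
    log = engine.run(params, obstacles=(), duration=duration, seed=seed)
    return analyze_hta(log)


# ---------------------------------------------------------------------------
# contact-induced asymmetry

def make_arena(size: float = 400.0, thickness: float = 20.0
               ) -> tuple[ObstacleSpec, ...]:
    """Four walls enclosing a square arena of inner side ``size`` (mm)."""
    h = size / 2.0 + thickness / 2.0
    long_side = size + 2.0 * thickness
    return (
        ObstacleSpec(cx_mm=-h, cy_mm=0.0, width_mm=thickness, height_mm=long_side),
        ObstacleSpec(cx_mm=h, cy_mm=0.0, width_mm=thickness, height_mm=long_side),
        ObstacleSpec(cx_mm=0.0, cy_mm=-h, width_mm=long_side, height_mm=thickness),
        ObstacleSpec(cx_mm=0.0, cy_mm=h, width_mm=long_side, height_mm=thickness),
    )


def _rect_distance_and_point(p: np.ndarray, ob: ObstacleSpec
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points to a rectangle and the nearest boundary points."""
    a = np.deg2rad(ob.angle_deg)
    c, s = np.cos(a), np.sin(a)
    dx = p[:, 0] - ob.cx_mm
    dy = p[:, 1] - ob.cy_mm
    qx = c * dx + s * dy
    qy = -s * dx + c * dy
    hw, hh = ob.width_mm / 2.0, ob.height_mm / 2.0
    cx = np.clip(qx, -hw, hw)
    cy = np.clip(qy, -hh, hh)
    dist = np.hypot(qx - cx, qy - cy)
    wx = ob.cx_mm + c * cx - s * cy
    wy = ob.cy_mm + s * cx + c * cy
    return dist, np.column_stack([wx, wy])


@dataclass
class CIAResult:
    """Binned map of relative protraction against nearby-wall position."""

    grid: np.ndarray        # (nbins, nbins) mean relative angle, NaN if empty
    counts: np.ndarray      # per-bin sample counts
    x_edges: np.ndarray     # head-frame forward coordinate bin edges, mm
    y_edges: np.ndarray     # head-frame lateral coordinate bin edges, mm
    baseline: float         # grand mean protraction angle over FAR, deg
    n_near: int             # whisks in the NEAR set
    n_far: int              # whisks in the FAR set
    log: SimLog | None = None


def analyze_cia(log: SimLog, walls: Sequence[ObstacleSpec],
                angle_source: str = "base") -> CIAResult:
    """Map mean protraction relative to a far-from-walls baseline.

    ``angle_source`` selects the protraction measure: ``"base"`` (whisker
    base angles, the default) reflects whisker *control*; ``"measured"``
    (the behavioural-convention shaft angles) additionally carries the
    physical deflection of whiskers against the walls, which dominates the
    map near contact and masks the control signal.
    """
    stem = {"base": "theta_base", "measured": "theta_meas"}[angle_source]
    p = log.meta["params"]
    dt = float(p["sample_dt"])
    fs = 1.0 / dt
    osc_T = float(p["oscillator_period"])

    mean_l = zero_phase_lowpass(log.whisker_matrix(stem, "L").mean(axis=1), fs)
    mean_r = zero_phase_lowpass(log.whisker_matrix(stem, "R").mean(axis=1), fs)
    fx = zero_phase_lowpass(log.df["fovea_x"].to_numpy(), fs)
    fy = zero_phase_lowpass(log.df["fovea_y"].to_numpy(), fs)
    nx = zero_phase_lowpass(log.df["neck_x"].to_numpy(), fs)
    ny = zero_phase_lowpass(log.df["neck_y"].to_numpy(), fs)

    # down-sample to one sample per whisk (nearest sample to each tick)
    t = log.df["t"].to_numpy()
    n_ticks = int(np.floor(t[-1] / osc_T))
    idx = np.round(np.arange(1, n_ticks + 1) * osc_T / dt).astype(int)
    idx = idx[idx < len(t)]

    ml8 = mean_l[idx]
    mr8 = mean_r[idx]
    nose = np.column_stack([fx[idx], fy[idx]])
    dists = np.empty((len(idx), len(walls)))
    points = []
    for j, w in enumerate(walls):
        d, q = _rect_distance_and_point(nose, w)
        dists[:, j] = d
        points.append(q)

    near_one = (dists <= _NEAR_DIST)
    far_all = (dists >= _FAR_DIST)
    near_mask = (near_one.sum(axis=1) == 1) & \
        ((far_all | near_one).all(axis=1)) & (~far_all.all(axis=1))
    far_mask = far_all.all(axis=1)
    n_near = int(near_mask.sum())
    n_far = int(far_mask.sum())
    if n_near == 0 or n_far == 0:
        raise ValueError("empty NEAR or FAR set: run too short or arena unexplored")

    baseline = float(np.concatenate([ml8[far_mask], mr8[far_mask]]).mean())

    # nearest wall point relative to the nose, in the head frame
    bearing = np.arctan2(fy[idx] - ny[idx], fx[idx] - nx[idx])
    edges = np.arange(-_CIA_HALF, _CIA_HALF + _CIA_BIN, _CIA_BIN)
    nb = len(edges) - 1
    ssum = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb), dtype=int)
    which_wall = np.argmax(near_one, axis=1)
    for k in np.flatnonzero(near_mask):
        j = which_wall[k]
        wp = points[j][k] - nose[k]
        cb, sb = np.cos(bearing[k]), np.sin(bearing[k])
        hx = cb * wp[0] + sb * wp[1]
        hy = -sb * wp[0] + cb * wp[1]
        for hy_signed, rel in ((hy, ml8[k] - baseline),
                               (-hy, mr8[k] - baseline)):
            ix = int(np.floor((hx + _CIA_HALF) / _CIA_BIN))
            iy = int(np.floor((hy_signed + _CIA_HALF) / _CIA_BIN))
            if 0 <= ix < nb and 0 <= iy < nb:
                ssum[ix, iy] += rel
                cnt[ix, iy] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
    return CIAResult(grid=grid, counts=cnt, x_edges=edges, y_edges=edges,
                     baseline=baseline, n_near=n_near, n_far=n_far, log=log)


def run_cia(params: Params, seed: int = 0, duration: float = 3600.0,
            arena_size: float = 400.0) -> CIAResult:
    """Arena exploration: thigmotaxis emerges and CIA is mapped near walls."""
    walls = make_arena(arena_size)
    log = engine.run(params, obstacles=walls, duration=duration, seed=seed)
    return analyze_cia(log, walls)


# ---------------------------------------------------------------------------
# spread reduction

@dataclass
class SRTrialSide:
    """Per-side outcome of one wall-approach trial."""

    trial: int
    side: str
    accepted: bool
    reason: str
    # per whisk type: (min, mean, max) spread from measured shaft angles
    spread: dict = field(default_factory=dict)
    # same, from whisker base angles (bending-free control)
    spread_base: dict = field(default_factory=dict)


@dataclass
class SRResult:
    """Spread statistics across wall-approach trials."""

    stats: dict            # {whisk type: {min/mean/max: trial-averaged deg}}
    stats_base: dict       # same, from base angles
    n_selected: int
    n_potential: int
    records: list = field(default_factory=list)


_WHISK_TYPES = ("pre", "first", "second")


def _spread_stats(log: SimLog, side: str, whisks: dict, stem: str) -> dict:
    mat = log.whisker_matrix(stem, side)
    spread = mat[:, _SPREAD_ROSTRAL - 1] - mat[:, _SPREAD_CAUDAL - 1]
    out = {}
    for typ in _WHISK_TYPES:
        w = whisks[typ]
        seg = spread[w.start:w.end + 1]
        out[typ] = {"min": float(seg.min()), "mean": float(seg.mean()),
                    "max": float(seg.max())}
    return out


def run_sr(params: Params, n_trials: int = 100, seed: int = 0) -> SRResult:
    """Randomized straight-line wall approaches with whisker control active.

    Each trial drives the fovea at a constant speed (uniform 10-50 mm/s)
    toward a wall angled uniformly within +/-10 degrees of perpendicular,
    starting 50 mm away and stopping 5 mm away (or one whisk after the
    second contact whisk on both sides).  Each trial contributes two
    potential side-samples; a side-sample is selected when no whisker (on
    either side) contacts during that side's pre-contact whisk and at least
    two whiskers on that side contact during its first contact whisk.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    records: list[SRTrialSide] = []
    sel_measured: dict[str, list] = {t: [] for t in _WHISK_TYPES}
    sel_base: dict[str, list] = {t: [] for t in _WHISK_TYPES}

    for trial in range(n_trials):
        wall_angle = rng.uniform(-10.0, 10.0)
        speed = rng.uniform(10.0, 50.0)
        thickness = 20.0
        wall = ObstacleSpec(cx_mm=_SR_START_DIST + thickness / 2.0, cy_mm=0.0,
                            width_mm=thickness, height_mm=300.0,
                            angle_deg=wall_angle)
        duration = (_SR_START_DIST - _SR_STOP_DIST) / speed
        pose0 = HeadPose(fovea=np.zeros(2),
                         neck=np.array([-params.fovea_neck_sep, 0.0]))

        def fovea_traj(t, v=speed):
            return np.array([v * t, 0.0])

        state = {"tick_count": 0, "contact_whisks": {"L": [], "R": []},
                 "whisk_has_contact": {"L": False, "R": False}}

        def stop_when(sim, row, st=state):
            n = params.n_whiskers_per_side
            for s_i, sname in enumerate(("L", "R")):
                any_c = any(row[f"contact_{sname}{i + 1}"] > 0 for i in range(n))
                st["whisk_has_contact"][sname] |= any_c
            if row["tick"]:
                for sname in ("L", "R"):
                    if st["whisk_has_contact"][sname]:
                        st["contact_whisks"][sname].append(st["tick_count"])
                    st["whisk_has_contact"][sname] = False
                st["tick_count"] += 1
                seconds = [st["contact_whisks"][s][1]
                           for s in ("L", "R")
                           if len(st["contact_whisks"][s]) >= 2]
                if len(seconds) == 2 and st["tick_count"] >= max(seconds) + 2:
                    return True
            return False

        log = engine.run(params, obstacles=(wall,), duration=duration,
                         seed=int(rng.integers(0, 2 ** 31 - 1)),
                         initial_pose=pose0, fovea_override=fovea_traj,
                         stop_when=stop_when)

        whisks = {"L": segment_whisks(log, "L"), "R": segment_whisks(log, "R")}
        for side in ("L", "R"):
            labelled = {w.label: w for w in whisks[side] if w.label}
            other = "R" if side == "L" else "L"
            rec = SRTrialSide(trial=trial, side=side, accepted=False, reason="")
            if not all(t in labelled for t in _WHISK_TYPES):
                rec.reason = "missing pre/first/second whisk"
            else:
                pre = labelled["pre"]
                contact_any = False
                for ws in (whisks[side], whisks[other]):
                    for w in ws:
                        if w.index == pre.index and w.has_contact:
                            contact_any = True
                if contact_any:
                    rec.reason = "contact during pre-contact whisk"
                elif labelled["first"].n_whiskers_contacting < 2:
                    rec.reason = "fewer than two whiskers in first contact whisk"
                else:
                    rec.accepted = True
                    rec.spread = _spread_stats(log, side, labelled, "theta_meas")
                    rec.spread_base = _spread_stats(log, side, labelled,
                                                    "theta_base")
                    for typ in _WHISK_TYPES:
                        sel_measured[typ].append(rec.spread[typ])
                        sel_base[typ].append(rec.spread_base[typ])
            records.append(rec)

    n_selected = sum(1 for r in records if r.accepted)

    def averaged(sel):
        out = {}
        for typ in _WHISK_TYPES:
            if sel[typ]:
                out[typ] = {k: float(np.mean([d[k] for d in sel[typ]]))
                            for k in ("min", "mean", "max")}
            else:
                out[typ] = {k: float("nan") for k in ("min", "mean", "max")}
        return out

    return SRResult(stats=averaged(sel_measured), stats_base=averaged(sel_base),
                    n_selected=n_selected, n_potential=2 * n_trials,
                    records=records)
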