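"""Motor pattern generation: whisking drive, head foveation and the
salience-to-protraction transform.

The oscillator ticks every ``oscillator_period`` seconds and emits a binary
whisking drive that is low during the first ``1 - duty_cycle`` of each cycle
(retraction) and high for the remainder (protraction), its falling edge
coinciding with the tick so that maximum protraction occurs at the tick.

Head movements are open-loop minimum-jerk trajectories of the fovea toward
the salience peak, re-planned (and therefore usually interrupted) at every
tick.

Whisker control implements a "minimal impingement, maximal contact"
transform: for each whisker and each salience-map cell, the protraction
angle at which the unperturbed shaft would pass through the cell is
precomputed; active cells then vote for their angles with weights that favour
strong salience and more caudal proposals, and the winning angle modulates
the whisker's maximum protraction away from its nominal value in proportion
to the map contrast and the modulation-strength parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .attention import GridSpec
from .params import Params
from .plane import FrameTransform, HeadPose, WhiskerMorph, arc_polyline

__all__ = [
    "Oscillator", "oscillator_step", "FoveationPlan", "min_jerk",
    "foveation_target", "GeomAngleTable", "build_geom_table",
    "proposed_angles", "arbitrated_angle", "map_contrast", "max_protraction",
    "WhiskerCommand", "whisk_step",
]

REACHABLE = 0
UNREACHABLE_FAR = 1
UNREACHABLE_NEAR = 2


# ---------------------------------------------------------------------------
# oscillator and whisking drive

def oscillator_step(t: float, params: Params) -> tuple[bool, int]:
    """Tick flag and whisking drive q at sample time ``t``.

    A tick fires on the first sample at or after each multiple of the
    oscillator period (excluding t = 0); q is 0 during the first
    ``1 - duty_cycle`` of each cycle and 1 during the rest.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    T = params.oscillator_period
    dt = params.sample_dt
    k_now = int(np.floor(t / T + 1e-9))
    k_prev = int(np.floor((t - dt) / T + 1e-9))
    tick = (k_now >= 1) and (k_now > k_prev)
    phase = t / T - k_now
    q = 1 if phase >= (1.0 - params.duty_cycle) - 1e-9 else 0
    return tick, q


class Oscillator:
    """Stateful wrapper tracking tick/drive over successive samples."""

    def __init__(self, params: Params):
        self.params = params
        self.tick = False
        self.q = 0

    def step(self, t: float) -> tuple[bool, int]:
        self.tick, self.q = oscillator_step(t, self.params)
        return self.tick, self.q


# ---------------------------------------------------------------------------
# head movement

@dataclass(frozen=True)
class FoveationPlan:
    """One pre-computed minimum-jerk fovea trajectory."""

    start: np.ndarray      # world, mm
    target: np.ndarray     # world, mm
    t0: float              # s
    duration: float        # s


def min_jerk(plan: FoveationPlan, t: float) -> np.ndarray:
    """Evaluate the quintic minimum-jerk position at time ``t``.

    Zero velocity and acceleration at both ends; ``t`` outside the plan's
    span clamps to the endpoints.
    """
    tau = (t - plan.t0) / plan.duration
    tau = min(max(tau, 0.0), 1.0)
    s = tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)
    return plan.start + s * (np.asarray(plan.target) - np.asarray(plan.start))


def foveation_target(spec: GridSpec, S_sel: np.ndarray,
                     pose: HeadPose) -> np.ndarray:
    """World location of the salience peak (the next foveation target).

    Ties are broken by the smallest distance to the current fovea, then by
    the lowest cell index; an all-zero map keeps the fovea where it is.
    """
    m = float(S_sel.max())
    if m <= 0.0:
        return pose.fovea.copy()
    flat = np.flatnonzero(S_sel.ravel() == m)
    tf = FrameTransform(pose)
    cand_world = tf.world_from_head(spec.centers[flat])
    if len(flat) == 1:
        return cand_world[0]
    d2 = np.sum((cand_world - pose.fovea) ** 2, axis=1)
    best = int(np.argmin(d2))      # argmin keeps the lowest index on ties
    return cand_world[best]


# ---------------------------------------------------------------------------
# salience -> maximum protraction (MIMC transform)

@dataclass(frozen=True)
class GeomAngleTable:
    """Per (whisker, cell) protraction angles that reach each cell.

    ``theta_geom[i, e]`` is the base angle at which whisker i's unperturbed
    arc passes through the center of cell e (flattened C order); ``code``
    distinguishes reachable cells from those beyond the whisker's reach
    (``UNREACHABLE_FAR``) or inside a radius the arc cannot attain
    (``UNREACHABLE_NEAR``; empty for the reference morphology, whose arcs
    span every radius from the base outward).
    """

    theta_geom: np.ndarray   # (n_whiskers, n_cells), deg; NaN where undefined
    code: np.ndarray         # (n_whiskers, n_cells), int


def build_geom_table(morphs: Sequence[WhiskerMorph], spec: GridSpec,
                     params: Params) -> GeomAngleTable:
    """Invert the whisker-arc geometry over the salience grid.

    Because the grid is head-centric and the morphology is rigid, the table
    is computed once per run.  For each whisker the arc is evaluated at a
    reference base angle; a cell at distance r from the base is reached at
    the arc length where the chord equals r, and the required base angle
    follows from the rigid rotation that carries the arc point onto the
    cell's direction.
    """
    nw = len(morphs)
    ncell = spec.nx * spec.ny
    theta = np.full((nw, ncell), np.nan)
    code = np.full((nw, ncell), UNREACHABLE_FAR, dtype=np.int8)
    theta_mid = 0.5 * (params.theta_min + params.theta_max)
    for i, m in enumerate(morphs):
        sgn = 1.0 if m.side == "left" else -1.0
        poly = arc_polyline(m, 0.0, m.rest_curvature, step=0.25)
        rel = poly - m.base_point
        chord = np.hypot(rel[:, 0], rel[:, 1])
        beta = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        beta[0] = beta[1]          # direction at the base is degenerate
        # first-crossing inversion of the (near-monotone) chord profile
        chord_mono = np.maximum.accumulate(chord)
        d = spec.centers - m.base_point
        r = np.hypot(d[:, 0], d[:, 1])
        psi = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        reach = r <= chord_mono[-1]
        idx = np.searchsorted(chord_mono, r[reach])
        idx = np.clip(idx, 1, len(chord_mono) - 1)
        c0 = chord_mono[idx - 1]
        c1 = chord_mono[idx]
        w = np.where(c1 > c0, (r[reach] - c0) / np.maximum(c1 - c0, 1e-12), 0.0)
        b = beta[idx - 1] + w * ((beta[idx] - beta[idx - 1] + 180.0) % 360.0 - 180.0)
        tg = sgn * (b - psi[reach])
        tg = (tg - (theta_mid - 180.0)) % 360.0 + (theta_mid - 180.0)
        theta[i, reach] = tg
        code[i, reach] = REACHABLE
    return GeomAngleTable(theta_geom=theta, code=code)


def proposed_angles(table: GeomAngleTable, params: Params
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per (whisker, cell) proposed maximum protraction angles.

    Reachable cells propose their geometric angle offset by the impingement
    angle and clipped to the allowed range; cells beyond the whisker's reach
    propose the maximum angle (the whisker 'reaches' forward).  Cells the
    whisker cannot meet at any *allowed* angle are excluded from arbitration
    (mask False): unreachable-near cells, and cells whose geometric angle
    falls caudal of the minimum protraction angle — voting those at the
    clipped minimum would hand locations the whisker can never touch the
    largest caudal-bias weight of all.
    """
    theta = np.where(table.code == REACHABLE,
                     np.clip(table.theta_geom + params.theta_imp,
                             params.theta_min, params.theta_max),
                     params.theta_max)
    mask = table.code != UNREACHABLE_NEAR
    caudal_out = (table.code == REACHABLE) & \
        (table.theta_geom + params.theta_imp < params.theta_min)
    mask = mask & ~caudal_out
    return theta, mask


def activity_floor(params: Params) -> float:
    """Salience level below which a map entry is not 'active'.

    Entries whose salience stays within the excitation noise floor (four
    noise gains) carry no vote in the protraction arbitration; the factor is
    uncritical (results plateau over a wide range) but without some floor
    the many weakly noisy cells, amplified by the caudal bias, would swamp
    the attended region.
    """
    return 4.0 * params.noise_gain


def arbitrated_angle(S_sel: np.ndarray, theta_prop: np.ndarray,
                     mask: np.ndarray, params: Params) -> np.ndarray:
    """Weighted-vote arbitration of proposed angles over active cells.

    Weight of an active cell e for whisker i:
    ``(activity_gain * S_e) ** activity_exponent *
    caudal_bias_base ** (-(theta_prop - theta_min) / (theta_max - theta_min))``
    — favouring strongly active cells and more caudal proposals, so the
    whisker tends to reach the first part of the active region it would meet
    during protraction.  Cells below the activity floor are not active and
    do not vote; whiskers with no active cells fall back to their nominal
    angles.
    """
    s = np.asarray(S_sel, float).ravel()
    s = np.where(s >= activity_floor(params), s, 0.0)
    act = (params.activity_gain * s) ** params.activity_exponent
    norm = (theta_prop - params.theta_min) / (params.theta_max - params.theta_min)
    caudal = params.caudal_bias_base ** (-norm)
    w = np.where(mask, caudal, 0.0) * act[None, :]
    den = w.sum(axis=1)
    num = (w * theta_prop).sum(axis=1)
    reps = theta_prop.shape[0] // params.n_whiskers_per_side
    theta_nom = np.tile(params.theta_nom, max(reps, 1))[:theta_prop.shape[0]]
    out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), theta_nom)
    return out


def map_contrast(S_sel: np.ndarray) -> float:
    """Michelson contrast of the selected salience map.

    ``C = (max - mean) / (max + mean)``, clipped to [0, 1]; 0 for a uniform
    (or empty) map, approaching 1 for a sparse map with a strong peak.  C
    gates how strongly the arbitration result displaces the maximum
    protraction angles from their nominal values.
    """
    m = float(S_sel.max(initial=0.0))
    if m <= 0.0:
        return 0.0
    mu = float(S_sel.mean())
    return float(np.clip((m - mu) / (m + mu), 0.0, 1.0))


def max_protraction(theta_hat: np.ndarray, contrast: float,
                    params: Params) -> np.ndarray:
    """Attentional modulation of the maximum protraction angle.

    ``theta_max_i = theta_nom_i + gamma * C * (theta_hat_i - theta_nom_i)``
    with gamma the modulation strength and C the map contrast.
    """
    theta_hat = np.asarray(theta_hat, float)
    reps = max(theta_hat.shape[0] // params.n_whiskers_per_side, 1) \
        if theta_hat.ndim else 1
    theta_nom = np.tile(params.theta_nom, reps)[:theta_hat.shape[0]] \
        if theta_hat.ndim else params.theta_nom
    return theta_nom + params.modulation_strength * contrast * (
        theta_hat - theta_nom)


# ---------------------------------------------------------------------------
# whisking pattern generation

@dataclass
class WhiskerCommand:
    """Instantaneous whisking command state for one side's whiskers."""

    theta_max_inst: np.ndarray   # deg, controlled maximum protraction
    theta_base: np.ndarray       # deg, current commanded base angle

    @property
    def theta_ret(self) -> np.ndarray:
        """Instantaneous maximum retraction angle (max minus amplitude)."""
        return self.theta_max_inst - self._amplitudes

    def __init__(self, theta_max_inst: np.ndarray, theta_base: np.ndarray,
                 amplitudes: np.ndarray):
        self.theta_max_inst = np.asarray(theta_max_inst, float).copy()
        self.theta_base = np.asarray(theta_base, float).copy()
        self._amplitudes = np.asarray(amplitudes, float)


def whisk_step(cmd: WhiskerCommand, q: int, dt: float,
               params: Params) -> WhiskerCommand:
    """First-order pursuit of the whisking target angle (Euler step).

    The target is the maximum protraction angle while the drive q is high
    and the maximum retraction angle otherwise; the commanded base angle
    relaxes toward it with time constant ``whisk_tau``.
    """
    target = cmd.theta_max_inst if q else cmd.theta_ret
    theta = cmd.theta_base + (dt / params.whisk_tau) * (target - cmd.theta_base)
    return WhiskerCommand(cmd.theta_max_inst, theta, cmd._amplitudes)
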