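"""Closed-loop simulation engine.

One :class:`Simulation` owns the full sensorimotor chain.  Each sample (at
125 Hz by default) proceeds in a fixed order: advance the oscillator; resolve
whisker bending and contact signals at the current pose and angles; deposit
tactile input and update both excitation maps (remapping the previous
sample's fields to the new pose); at oscillator ticks, update the
inhibition-of-return memory, recompute salience, re-select the attended
channel and re-plan the head movement; every sample, recompute salience for
whisker control, run the salience-to-protraction transform and the whisking
dynamics; finally move the fovea along its minimum-jerk plan and drag the
neck behind it.

Randomness is split into three independent streams spawned from the master
seed (tactile noise, 'other' noise, 'other' target locations) so runs are
bitwise reproducible and component-level perturbations stay decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import attention, motor, plane
from .attention import GridSpec, IORMemory, NoiseState
from .params import ObstacleSpec, Params
from .plane import HeadPose, _MorphArrays, build_morphology, pack_obstacles

__all__ = ["SimLog", "Simulation", "run", "LOG_SCHEMA_VERSION"]

LOG_SCHEMA_VERSION = 1

_SIDES = ["L", "R"]


def _whisker_columns(n: int) -> list[str]:
    cols = []
    for stem in ("theta_base", "theta_max", "theta_meas", "contact",
                 "contact_x", "contact_y"):
        for s in _SIDES:
            for i in range(1, n + 1):
                cols.append(f"{stem}_{s}{i}")
    return cols


@dataclass
class SimLog:
    """Per-sample record of one simulation run."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_whiskers_per_side(self) -> int:
        return int(self.meta.get("n_whiskers_per_side", 7))

    def whisker_matrix(self, stem: str, side: str) -> np.ndarray:
        """(n_samples, n_whiskers) matrix of one per-whisker quantity."""
        n = self.n_whiskers_per_side
        cols = [f"{stem}_{side}{i}" for i in range(1, n + 1)]
        return self.df[cols].to_numpy()


class Simulation:
    """State and per-sample stepping of the closed sensorimotor loop."""

    def __init__(self, params: Params,
                 obstacles: Sequence[ObstacleSpec] = (),
                 seed: int = 0,
                 initial_pose: HeadPose | None = None,
                 fovea_override: Callable[[float], np.ndarray] | None = None,
                 mirror_stochastic: bool = False):
        self.params = params
        self.obstacles = pack_obstacles(list(obstacles))
        self.spec = GridSpec(params)
        self.morphs = build_morphology(params)
        self._ma = _MorphArrays(self.morphs)
        self._gains = np.tile(params.sensing_gains, 2)
        self.fovea_override = fovea_override
        self.mirror = mirror_stochastic

        ss = np.random.SeedSequence(seed)
        child = ss.spawn(3)
        self._rng_tnoise = np.random.default_rng(child[0])
        self._rng_onoise = np.random.default_rng(child[1])
        self._rng_target = np.random.default_rng(child[2])

        self.pose = initial_pose or HeadPose(fovea=np.zeros(2),
                                             neck=np.array([-params.fovea_neck_sep, 0.0]))
        self.pose.check(params.fovea_neck_sep, tol=1e-6)

        nw2 = 2 * params.n_whiskers_per_side
        self.theta_nom2 = np.tile(params.theta_nom, 2)
        self.amplitudes2 = np.tile(params.amplitudes, 2)
        self.theta_base = self.theta_nom2.copy()
        self.theta_max_inst = self.theta_nom2.copy()

        self.E_t = self.spec.zeros()
        self.E_o = self.spec.zeros()
        self.noise_t = NoiseState.create(self.spec, params)
        self.noise_o = NoiseState.create(self.spec, params)
        self.ior = IORMemory()
        self.channel = "other"
        self.plan: motor.FoveationPlan | None = None

        # MIMC transform tables (static in the head frame)
        table = motor.build_geom_table(self.morphs, self.spec, params)
        theta_prop, mask = motor.proposed_angles(table, params)
        self.geom_table = table
        self.theta_prop = theta_prop
        self.prop_mask = mask
        norm = (theta_prop - params.theta_min) / (params.theta_max - params.theta_min)
        B = np.where(mask, params.caudal_bias_base ** (-norm), 0.0)
        self._W_den = np.ascontiguousarray(B)
        self._W_num = np.ascontiguousarray(B * theta_prop)

        self.n_step = 0
        self.last_target = self.pose.fovea.copy()
        self._kappa_pert = self._ma.kappa.copy()
        self._lengths2 = self._ma.length
        self._clamped_any = False

    # -- helpers --------------------------------------------------------

    def _measured_angles(self, kappa_pert: np.ndarray) -> np.ndarray:
        """Protraction angle of the base-to-(2/3 shaft) chord, in degrees."""
        p = self.params
        s = (2.0 / 3.0) * self._lengths2
        side = self._ma.side
        alpha0 = np.where(side > 0, np.pi - np.deg2rad(self.theta_base),
                          np.deg2rad(self.theta_base) - np.pi)
        kap = -side * kappa_pert
        small = np.abs(kap) < 1e-12
        kap_safe = np.where(small, 1.0, kap)
        dx = np.where(small, s * np.cos(alpha0),
                      (np.sin(alpha0 + kap_safe * s) - np.sin(alpha0)) / kap_safe)
        dy = np.where(small, s * np.sin(alpha0),
                      (np.cos(alpha0) - np.cos(alpha0 + kap_safe * s)) / kap_safe)
        beta = np.degrees(np.arctan2(dy, dx))
        theta = np.where(side > 0, 180.0 - beta, beta + 180.0)
        return theta % 360.0

    def _salience_pair(self, t: float):
        """Current inhibition and both salience maps at the current pose."""
        H_obs = attention.obstacle_inhibition(self.spec, self.obstacles, self.pose)
        H_ior = attention.ior_field(self.spec, self.ior, self.pose, self.params)
        H = attention.inhibition(H_obs, H_ior, self.params)
        S_t = attention.salience(self.E_t, H)
        S_o = attention.salience(self.E_o, H)
        return H, S_t, S_o

    # -- the per-sample update ------------------------------------------

    def step(self) -> dict:
        """Advance one sample; returns the log row as a dict of scalars."""
        p = self.params
        t = self.n_step * p.sample_dt
        tick, q = motor.oscillator_step(t, p)

        # (2) quasistatic bending and contact at the current configuration
        kappa, delta, contact, cpoints, clamped = plane.bend_all(
            self._ma, self.theta_base, self.pose, self.obstacles, p,
            gains=self._gains)
        self._kappa_pert = kappa
        if clamped.any():
            self._clamped_any = True

        # (3) sensory deposit and excitation updates (remap to the new pose)
        tf = plane.FrameTransform(self.pose)
        has_contact = contact > 0.0
        I_t = self.spec.zeros()
        if has_contact.any():
            pts_head = tf.head_from_world(cpoints[has_contact])
            I_t = attention.deposit_blobs(self.spec, I_t, pts_head,
                                          contact[has_contact],
                                          p.tactile_blob_width)
        allowed = None
        if tick and self.obstacles.shape[0]:
            allowed = attention.obstacle_inhibition(
                self.spec, self.obstacles, self.pose) < 0.5
        I_o = attention.other_input(self.spec, tick, self._rng_target, p,
                                    mirror=self.mirror, allowed=allowed)
        pose_prev = getattr(self, "_pose_prev", self.pose)
        self.E_t = attention.update_excitation(
            self.spec, self.E_t, I_t, pose_prev, self.pose,
            self.noise_t.step(self._rng_tnoise, self.mirror), p.noise_gain)
        # the endogenous channel holds a single active region: when a new
        # target blob is generated (at a tick) the old one is dropped
        self.E_o = attention.update_excitation(
            self.spec, self.E_o, I_o, pose_prev, self.pose,
            self.noise_o.step(self._rng_onoise, self.mirror), p.noise_gain,
            keep_memory=not tick)

        # (4) at ticks: IOR, channel re-selection, head re-planning
        if tick:
            self.ior = attention.ior_step(self.ior, self.pose.fovea, t, p)
        H, S_t, S_o = self._salience_pair(t)
        if tick:
            self.channel = attention.select_channel(S_t, S_o, self.channel)
            S_sel = S_t if self.channel == "tactile" else S_o
            self.last_target = motor.foveation_target(self.spec, S_sel, self.pose)
            self.plan = motor.FoveationPlan(
                start=self.pose.fovea.copy(), target=self.last_target.copy(),
                t0=t, duration=p.foveation_period)

        # (5) whisker control from the selected salience map
        S_sel = S_t if self.channel == "tactile" else S_o
        s_flat = S_sel.ravel()
        s_flat = np.where(s_flat >= motor.activity_floor(p), s_flat, 0.0)
        act = (p.activity_gain * s_flat) ** p.activity_exponent
        den = self._W_den @ act
        num = self._W_num @ act
        theta_hat = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0),
                             self.theta_nom2)
        C = motor.map_contrast(S_sel)
        self.theta_max_inst = self.theta_nom2 + p.modulation_strength * C * (
            theta_hat - self.theta_nom2)
        target_angle = np.where(q, self.theta_max_inst,
                                self.theta_max_inst - self.amplitudes2)
        self.theta_base = self.theta_base + (p.sample_dt / p.whisk_tau) * (
            target_angle - self.theta_base)

        # log row reflects the state *during* this sample
        theta_meas = self._measured_angles(kappa)
        row = {
            "t": t,
            "fovea_x": self.pose.fovea[0], "fovea_y": self.pose.fovea[1],
            "neck_x": self.pose.neck[0], "neck_y": self.pose.neck[1],
            "bearing_deg": np.degrees(self.pose.bearing),
            "tick": int(tick), "q": q,
            "channel": 1 if self.channel == "tactile" else 0,
            "target_x": self.last_target[0], "target_y": self.last_target[1],
            "clamped": int(clamped.any()),
        }
        n = p.n_whiskers_per_side
        for stem, arr in (("theta_base", self.theta_base),
                          ("theta_max", self.theta_max_inst),
                          ("theta_meas", theta_meas),
                          ("contact", contact),
                          ("contact_x", cpoints[:, 0]),
                          ("contact_y", cpoints[:, 1])):
            for k, s in enumerate(_SIDES):
                for i in range(n):
                    row[f"{stem}_{s}{i + 1}"] = arr[k * n + i]

        # (6) head movement: fovea along the plan (or override), neck drags
        self._pose_prev = self.pose
        t_next = t + p.sample_dt
        if self.fovea_override is not None:
            new_fovea = np.asarray(self.fovea_override(t_next), float)
        elif self.plan is not None:
            new_fovea = motor.min_jerk(self.plan, t_next)
        else:
            new_fovea = self.pose.fovea
        if not np.array_equal(new_fovea, self.pose.fovea):
            self.pose = plane.step_neck(self.pose, new_fovea, p.fovea_neck_sep)

        self.n_step += 1
        return row


def run(params: Params, obstacles: Sequence[ObstacleSpec] = (),
        duration: float = 30.0, seed: int = 0,
        initial_pose: HeadPose | None = None,
        fovea_override: Callable[[float], np.ndarray] | None = None,
        mirror_stochastic: bool = False,
        stop_when: Callable[[Simulation, dict], bool] | None = None) -> SimLog:
    """Run a full simulation and return its :class:`SimLog`.

    ``duration / sample_dt + 1`` samples are produced (time stamps 0 to
    ``duration`` inclusive); a fixed seed gives a bitwise reproducible log.
    ``stop_when(sim, row)``, if given, ends the run early after the sample
    for which it returns True.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    sim = Simulation(params, obstacles, seed=seed, initial_pose=initial_pose,
                     fovea_override=fovea_override,
                     mirror_stochastic=mirror_stochastic)
    n_samples = int(round(duration / params.sample_dt)) + 1
    cols = ["t", "fovea_x", "fovea_y", "neck_x", "neck_y", "bearing_deg",
            "tick", "q", "channel", "target_x", "target_y", "clamped"]
    cols += _whisker_columns(params.n_whiskers_per_side)
    data = {c: np.empty(n_samples) for c in cols}
    n_used = n_samples
    for k in range(n_samples):
        row = sim.step()
        for c in cols:
            data[c][k] = row[c]
        if stop_when is not None and stop_when(sim, row):
            n_used = k + 1
            break
    df = pd.DataFrame({c: data[c][:n_used] for c in cols})
    meta = {
        "schema_version": LOG_SCHEMA_VERSION,
        "seed": int(seed),
        "duration_s": float(duration),
        "n_whiskers_per_side": int(params.n_whiskers_per_side),
        "params": params.to_dict(),
        "clamped_any": bool(sim._clamped_any),
    }
    return SimLog(df=df, meta=meta)
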