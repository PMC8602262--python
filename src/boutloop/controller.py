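"""Feedback-control model of the acute optomotor reaction.

The controller senses the shown grating velocity with a fixed 220 ms
processing delay, splits it into forward and reverse components by
rectification, and integrates the recombined drive in a leaky *velocity
integrator* (sensory drive V, clipped to [0, 1]).  The sensory drive feeds a
*motor output generator* whose activity (motor drive D) triggers a *motor
command generator* when it reaches a threshold; the output is then a binary
20 mm/s swim velocity.  A leaky *motor integrator* ("tiredness" M, clipped
at 1) accumulates the motor output and inhibits the motor drive, so bouts
have finite length even under sustained sensory drive, and a self-excitation
loop on the command generator keeps bouts alive once started.

Discrete update at step size dt (exponential Euler, exact for
piecewise-constant input):

    s_in = w_f * max(u, 0) - w_r * max(-u, 0),  u = shown grating (t - 220 ms)
    V   <- clip01( V * exp(-dt/tau_s) + s_in * (1 - exp(-dt/tau_s)) )
    D    = max(0, V + w_s * b_prev - w_i * M)
    b    = 1 if D >= thr else 0
    M   <- min(1, M * exp(-dt/tau_m) + w_m * b * (1 - exp(-dt/tau_m)))
    output velocity = 20 mm/s * b
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .reafference import (
    DT,
    NORMAL,
    Protocol,
    ReafferenceCondition,
    TailRecording,
    bout_intervals,
    enumerate_conditions,
)

__all__ = [
    "ControllerParams",
    "ControllerState",
    "ModelTrajectory",
    "REFERENCE_PARAMS",
    "step",
    "simulate",
    "simulate_protocol",
    "run_model_trial",
    "condition_summary",
    "encode_conditions",
]

#: fixed sensory processing delay (s); not a fitted parameter.
SENSORY_DELAY_S = 0.220

#: binary swim speed of the model while in a bout (mm/s).
SWIM_SPEED = 20.0


@dataclass(frozen=True)
class ControllerParams:
    """The eight fitted parameters of the feedback controller.

    Weights of the forward/reverse velocity sensors are per mm/s of grating
    velocity; time constants are in seconds; the threshold and the
    self-excitation, motor-integration and inhibition weights live on the
    dimensionless [0, 1] scale of the integrator activities.
    """

    omega_f: float   # forward velocity sensor weight (1 / (mm/s))
    omega_r: float   # reverse velocity sensor weight (1 / (mm/s))
    tau_s: float     # velocity-integrator time constant (s)
    thr: float       # motor command threshold
    omega_s: float   # self-excitation of the command generator
    omega_m: float   # motor-integrator input weight
    tau_m: float     # motor-integrator time constant (s)
    omega_i: float   # tiredness inhibition weight

    def __post_init__(self) -> None:
        for name in ("omega_f", "omega_r", "tau_s", "thr", "omega_s",
                     "omega_m", "tau_m", "omega_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.omega_f, self.omega_r, self.tau_s, self.thr,
                         self.omega_s, self.omega_m, self.tau_m, self.omega_i])

    @staticmethod
    def from_array(a) -> "ControllerParams":
        a = np.asarray(a, dtype=float)
        return ControllerParams(*a.tolist())


#: Reference parameter set used throughout tests and examples.  Obtained by
#: fitting the controller (genetic algorithm, behaviour-recovery objective)
#: to a duration table exhibiting the acute-reaction trends of the assay:
#: bout duration decreasing with gain and increasing with lag, V-shaped
#: interbout duration versus gain, and longer interbouts after non-shunted
#: than after shunted lags.
REFERENCE_PARAMS = ControllerParams(
    omega_f=0.045,
    omega_r=0.015,
    tau_s=0.5,
    thr=0.25,
    omega_s=0.12,
    omega_m=1.3,
    tau_m=2.4,
    omega_i=0.6,
)


@dataclass
class ControllerState:
    """Dynamic node activities of the controller."""

    V: float = 0.0  # sensory drive, [0, 1]
    M: float = 0.0  # tiredness, [0, 1]
    D: float = 0.0  # motor drive, >= 0
    b: int = 0      # bout flag


def step(state: ControllerState, u: float, params: ControllerParams,
         dt: float = DT) -> ControllerState:
    """Advance the controller one step given the delayed grating velocity u.

    ``u`` is the grating velocity 220 ms before the current time; managing
    that delay line is the caller's job (see :func:`simulate`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(u):
        raise ValueError("non-finite input velocity")
    p = params
    a_s = math.exp(-dt / p.tau_s)
    a_m = math.exp(-dt / p.tau_m)
    s_in = p.omega_f * u if u > 0 else p.omega_r * u
    V = min(max(state.V * a_s + s_in * (1.0 - a_s), 0.0), 1.0)
    D = max(V + p.omega_s * state.b - p.omega_i * state.M, 0.0)
    b = 1 if D >= p.thr else 0
    M = min(state.M * a_m + p.omega_m * b * (1.0 - a_m), 1.0)
    return ControllerState(V=V, M=M, D=D, b=b)


# ---------------------------------------------------------------------------
# condition encoding for the compiled loop
# ---------------------------------------------------------------------------

def encode_conditions(conds: list[ReafferenceCondition], dt: float = DT):
    """Pack conditions into the flat arrays the compiled loop consumes."""
    m = len(conds)
    kind = np.zeros(m, dtype=np.int64)
    gain = np.ones(m)
    lagn = np.zeros(m, dtype=np.int64)
    shunt = np.zeros(m, dtype=np.int8)
    prof = np.ones((m, 4), dtype=np.int8)
    for i, c in enumerate(conds):
        if c.kind == "gain":
            kind[i] = _core.KIND_GAIN
            gain[i] = c.gain
        elif c.kind == "lag":
            kind[i] = _core.KIND_LAG
            lagn[i] = -1 if math.isinf(c.lag_ms) else int(round(c.lag_ms / 1000.0 / dt))
            shunt[i] = 1 if c.shunted else 0
        else:
            kind[i] = _core.KIND_DROP
            prof[i] = [int(d) for d in c.profile]
    return kind, gain, lagn, shunt, prof


_EMPTY = encode_conditions([NORMAL])


@dataclass
class ModelTrajectory:
    """Closed-loop state and stimulus traces of one simulation."""

    time: np.ndarray
    grating_cmd: np.ndarray
    grating_shown: np.ndarray
    V: np.ndarray
    M: np.ndarray
    D: np.ndarray
    bout_flag: np.ndarray
    dt: float
    onsets: np.ndarray    # sample indices of bout onsets
    offsets: np.ndarray   # sample indices of bout offsets (-1 if unfinished)
    n_bouts: int

    @property
    def est_velocity(self) -> np.ndarray:
        return SWIM_SPEED * self.bout_flag.astype(float)

    def as_recording(self) -> TailRecording:
        """View the binary-velocity trajectory as a TailRecording."""
        return TailRecording(
            time=self.time, tail_angle=np.zeros_like(self.time),
            grating_cmd=self.grating_cmd, grating_shown=self.grating_shown,
            vigor=self.est_velocity, est_velocity=self.est_velocity,
            bout_flag=self.bout_flag.astype(np.int8), multiplier=1.0, dt=self.dt,
        )


def _run(params_per_trial, cmd, trial_of_sample, dt, t_policy,
         bconds, tconds, stop_at_bout=-1) -> ModelTrajectory:
    delay_n = int(round(SENSORY_DELAY_S / dt))
    seg_n = int(round(0.075 / dt))
    bk, bg, bl, bs, bp = bconds
    tk, tg, tl, ts, tp = tconds
    out = _core.run_session(
        params_per_trial, cmd, dt, delay_n, seg_n, trial_of_sample,
        t_policy, bk, bg, bl, bs, bp, tk, tg, tl, ts, tp,
        stop_at_bout, SWIM_SPEED,
    )
    V, M, D, b, shown, onsets, offsets, nb, end_t = out
    onsets = onsets[:nb]
    offsets = offsets[:nb]
    time = np.arange(cmd.size) * dt
    return ModelTrajectory(time=time, grating_cmd=cmd, grating_shown=shown,
                           V=V, M=M, D=D, bout_flag=b, dt=dt,
                           onsets=onsets, offsets=offsets, n_bouts=nb)


def simulate(params: ControllerParams, grating_cmd: np.ndarray,
             cond: ReafferenceCondition = NORMAL, dt: float = DT,
             seed: int | None = None) -> ModelTrajectory:
    """Closed-loop simulation under a single reafference condition.

    The model is deterministic; ``seed`` is accepted only for interface
    symmetry with stochastic behavers.
    """
    cmd = np.ascontiguousarray(grating_cmd, dtype=float)
    p = params.to_array()[None, :]
    trial_of_sample = np.zeros(cmd.size, dtype=np.int64)
    bconds = encode_conditions([cond], dt)
    t_policy = np.ones(1, dtype=np.int8)
    return _run(p, cmd, trial_of_sample, dt, t_policy, bconds, _EMPTY)


def simulate_protocol(params: ControllerParams | np.ndarray, protocol: Protocol,
                      seed: int = 0) -> ModelTrajectory:
    """Run the controller through a full experimental protocol.

    ``params`` may be a single parameter set or a per-trial (n_trials, 8)
    array implementing a scheduled parameter drift.  Per-bout random
    condition draws (acute-reaction and whole-brain protocols) are pre-drawn
    from the seeded generator, making the run deterministic given the seed.
    """
    dt = protocol.dt
    cmd = protocol.grating_cmd()
    n = cmd.size
    if isinstance(params, ControllerParams):
        pmat = np.tile(params.to_array(), (protocol.n_trials, 1))
    else:
        pmat = np.ascontiguousarray(params, dtype=float)
        if pmat.shape != (protocol.n_trials, 8):
            raise ValueError("per-trial parameter array must be (n_trials, 8)")

    n_blank = int(round(protocol.pre_blank_s / dt))
    n_trial = int(round(protocol.trial_duration_s / dt))
    idx = (np.arange(n) - n_blank) // n_trial
    trial_of_sample = np.clip(idx, 0, protocol.n_trials - 1).astype(np.int64)

    t_policy = np.array([0 if t.policy == "fixed" else 1 for t in protocol.trials],
                        dtype=np.int8)
    tconds = encode_conditions(
        [t.condition if t.policy == "fixed" else NORMAL for t in protocol.trials], dt)
    if t_policy.any():
        # pre-draw a generous number of per-bout conditions for the random
        # phases; they are consumed in bout order, so the session is
        # deterministic given the seed.
        rng = np.random.default_rng(seed)
        cap = n // 8 + 8
        random_spec = next(t for t in protocol.trials if t.policy != "fixed")
        conds = [_draw_from_policy(random_spec.policy, rng) for _ in range(cap)]
        bconds = encode_conditions(conds, dt)
    else:
        bconds = _EMPTY
    return _run(pmat, cmd, trial_of_sample, dt, t_policy, bconds, tconds)


def _draw_from_policy(policy: str, rng: np.random.Generator) -> ReafferenceCondition:
    if policy == "uniform18":
        u = enumerate_conditions()
        return u[rng.integers(len(u))]
    if policy == "normal_or_openloop":
        return NORMAL if rng.integers(2) == 0 else OPEN_LOOP_


# late import alias to avoid clashing with the NORMAL import above
from .reafference import OPEN_LOOP as OPEN_LOOP_  # noqa: E402


def run_model_trial(params: ControllerParams,
                    cond2: ReafferenceCondition,
                    dt: float = DT,
                    seed: int | None = None) -> tuple[float, float] | None:
    """One short model-test trial; returns second-bout metrics.

    The trial is 300 ms of static grating followed by 9.7 s of forward
    motion at 10 mm/s.  The first bout receives normal reafference and the
    second the probed condition; the trial terminates at the onset of a
    third bout, whose occurrence validates the output.  Returns
    ``(bout2_duration_ms, interbout2_duration_ms)`` or ``None`` when the
    model produced no third bout within the trial.
    """
    n_static = int(round(0.300 / dt))
    n_move = int(round(9.7 / dt))
    cmd = np.zeros(n_static + n_move)
    cmd[n_static:] = 10.0
    p = params.to_array()[None, :]
    trial_of_sample = np.zeros(cmd.size, dtype=np.int64)
    bconds = encode_conditions([NORMAL, cond2, NORMAL], dt)
    traj = _run(p, cmd, trial_of_sample, dt, np.ones(1, dtype=np.int8),
                bconds, _EMPTY, stop_at_bout=2)
    if traj.n_bouts < 3:
        return None
    on2, off2 = traj.onsets[1], traj.offsets[1]
    on3 = traj.onsets[2]
    if off2 < 0:
        return None
    bout2_ms = (off2 - on2) * dt * 1000.0
    interbout2_ms = (on3 - off2) * dt * 1000.0
    return bout2_ms, interbout2_ms


def condition_summary(params: ControllerParams,
                      conditions: list[ReafferenceCondition] | None = None,
                      dt: float = DT) -> np.ndarray:
    """36-value acute-reaction table: per-condition second-bout duration
    (first 18 entries) and subsequent interbout duration (last 18), in ms.

    Entries are NaN for conditions where the model produced no third bout.
    """
    conds = enumerate_conditions() if conditions is None else conditions
    bouts = np.full(len(conds), np.nan)
    inter = np.full(len(conds), np.nan)
    for i, c in enumerate(conds):
        out = run_model_trial(params, c, dt=dt)
        if out is not None:
            bouts[i], inter[i] = out
    return np.concatenate([bouts, inter])
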