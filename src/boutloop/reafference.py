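"""Virtual closed-loop optomotor assay.

Head-restrained larval zebrafish swim "virtually" in this assay: the tail
trace is reduced to a *vigor* signal (sliding standard deviation), vigor is
converted into an estimated forward velocity, and during detected swim bouts
the estimated velocity is subtracted from the command velocity of a moving
grating, so the fish experiences visual reafference as if it were freely
swimming.  This module implements that loop and the reafference
perturbations used to probe it (gain changes, lags, shunted lags and
gain-drop profiles), plus the four experimental protocols built from them.

Conventions: positive grating velocity is forward (caudal to rostral) optic
flow in mm/s; tail angle is the cumulative sum of eight segment angles in
radians; all series live on a uniform 5 ms grid unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DT",
    "ReafferenceCondition",
    "NORMAL",
    "OPEN_LOOP",
    "TailRecording",
    "TrialSpec",
    "Protocol",
    "CalibrationError",
    "compute_vigor",
    "calibrate_multiplier",
    "detect_bouts_online",
    "bout_intervals",
    "apply_reafference",
    "redundant_conditions",
    "enumerate_conditions",
    "condition_index",
    "build_protocol",
    "run_closed_loop_session",
]

#: default simulation / analysis grid (s); matches 200 fps tracking.
DT = 0.005

#: fixed forward speed of the command grating (mm/s).
BASE_VELOCITY = 10.0

GAIN_VALUES = (0.0, 0.33, 0.66, 1.0, 1.33, 1.66, 2.0)
LAG_VALUES_MS = (0.0, 75.0, 150.0, 225.0, 300.0, math.inf)
SHUNTED_LAG_VALUES_MS = (75.0, 150.0, 225.0, 300.0)
GAIN_DROP_PROFILES = ("1111", "0111", "0011", "0001", "0000", "1110", "1100", "1000")

#: length of one gain-drop segment (s); four segments tile the first 300 ms.
DROP_SEGMENT_S = 0.075


class CalibrationError(RuntimeError):
    """Raised when the vigor-to-velocity calibration cannot be performed."""


@dataclass(frozen=True)
class ReafferenceCondition:
    """One reafference perturbation.

    kind
        ``"gain"`` — reafference is ``gain`` times the estimated velocity,
        gated to the bout; ``gain`` 0 is open-loop, 1 is normal.
        ``"lag"`` — gain-1 reafference delayed by ``lag_ms`` relative to bout
        onset. Non-shunted lag persists ``lag_ms`` past bout offset (excess
        reafference after the bout); shunted lag is cut at bout offset.
        ``"gain_drop"`` — the first 300 ms of the bout is tiled by four
        75 ms segments whose gains are the digits of ``profile``; gain is 1
        past 300 ms.
    """

    kind: str
    gain: float = 1.0
    lag_ms: float = 0.0
    shunted: bool = False
    profile: str = "1111"

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "lag", "gain_drop"):
            raise ValueError(f"unknown reafference kind: {self.kind!r}")
        if self.kind == "gain_drop" and (
            len(self.profile) != 4 or any(c not in "01" for c in self.profile)
        ):
            raise ValueError(f"invalid gain-drop profile: {self.profile!r}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def of_gain(gain: float) -> "ReafferenceCondition":
        return ReafferenceCondition("gain", gain=float(gain))

    @staticmethod
    def of_lag(lag_ms: float, shunted: bool = False) -> "ReafferenceCondition":
        return ReafferenceCondition("lag", lag_ms=float(lag_ms), shunted=shunted)

    @staticmethod
    def of_profile(profile: str) -> "ReafferenceCondition":
        return ReafferenceCondition("gain_drop", profile=profile)

    @property
    def label(self) -> str:
        if self.kind == "gain":
            if self.gain == 1.0:
                return "normal"
            if self.gain == 0.0:
                return "open_loop"
            return f"gain_{self.gain:g}"
        if self.kind == "lag":
            if self.lag_ms == 0.0:
                return "normal"
            if math.isinf(self.lag_ms):
                return "open_loop"
            suffix = "_shunted" if self.shunted else ""
            return f"lag_{self.lag_ms:g}{suffix}"
        if self.profile == "1111":
            return "normal"
        return f"drop_{self.profile}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


NORMAL = ReafferenceCondition.of_gain(1.0)
OPEN_LOOP = ReafferenceCondition.of_gain(0.0)


# ---------------------------------------------------------------------------
# vigor, calibration, online bout detection
# ---------------------------------------------------------------------------

def compute_vigor(tail_angle: np.ndarray, dt: float = DT, window_ms: float = 50.0) -> np.ndarray:
    """Causal sliding standard deviation of the tail trace ("vigor").

    The window is trailing (real-time computable) and its length defaults to
    50 ms.  Population standard deviation is used, so a fast sinusoid of
    amplitude ``A`` plateaus at ``A / sqrt(2)``.
    """
    if dt <= 0:
        raise ValueError("sampling period must be positive")
    n_win = max(1, int(round(window_ms / 1000.0 / dt)))
    s = pd.Series(np.asarray(tail_angle, dtype=float))
    vigor = s.rolling(n_win, min_periods=1).std(ddof=0).to_numpy()
    return vigor


def calibrate_multiplier(
    vigor: np.ndarray, bout_flag: np.ndarray, target_median: float = 20.0
) -> float:
    """Multiplier converting vigor (rad) to estimated velocity (mm/s).

    Chosen so the median of ``vigor * multiplier`` over all in-bout samples
    equals ``target_median`` (20 mm/s, the free-swimming bout velocity).
    """
    bout_flag = np.asarray(bout_flag).astype(bool)
    if not bout_flag.any():
        raise CalibrationError("no bouts detected; cannot calibrate vigor multiplier")
    med = float(np.median(np.asarray(vigor, dtype=float)[bout_flag]))
    if med <= 0:
        raise CalibrationError("median in-bout vigor is zero; cannot calibrate")
    return target_median / med


def detect_bouts_online(est_velocity: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Online bout flag: 1 wherever estimated velocity exceeds 2 mm/s."""
    return (np.asarray(est_velocity, dtype=float) > threshold).astype(np.int8)


def bout_intervals(bout_flag: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``(onset, offset)`` index pairs of the bout flag."""
    b = np.asarray(bout_flag).astype(np.int8)
    d = np.diff(np.concatenate(([0], b, [0])))
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    return list(zip(onsets.tolist(), offsets.tolist()))


# ---------------------------------------------------------------------------
# reafference transformations
# ---------------------------------------------------------------------------

def apply_reafference(
    est_velocity: np.ndarray,
    bout_flag: np.ndarray,
    cond: ReafferenceCondition,
    base_velocity: float | np.ndarray = BASE_VELOCITY,
    dt: float = DT,
) -> np.ndarray:
    """Grating velocity shown to the fish under one reafference condition.

    The shown velocity is ``base - r(t)`` where ``r`` is the reafference
    stream derived from the in-bout estimated velocity per the condition.
    The series is returned on the input grid; no resampling happens here.
    """
    v = np.asarray(est_velocity, dtype=float)
    b = np.asarray(bout_flag).astype(bool)
    n = v.size
    r = np.zeros(n)
    intervals = bout_intervals(b)

    if cond.kind == "gain":
        r = cond.gain * v * b
    elif cond.kind == "lag":
        if not math.isinf(cond.lag_ms):
            k = int(round(cond.lag_ms / 1000.0 / dt))
            for on, off in intervals:
                src = v[on:off]
                start = on + k
                if start >= n:
                    continue
                if cond.shunted:
                    stop = min(off, n)
                else:
                    stop = min(off + k, n)
                m = stop - start
                if m > 0:
                    r[start:stop] += src[:m]
    else:  # gain_drop
        seg = int(round(DROP_SEGMENT_S / dt))
        r = v * b
        for on, off in intervals:
            for i, digit in enumerate(cond.profile):
                if digit == "0":
                    a = min(on + i * seg, off)
                    z = min(on + (i + 1) * seg, off)
                    r[a:z] = 0.0
    return np.asarray(base_velocity, dtype=float) - r


def redundant_conditions() -> list[ReafferenceCondition]:
    """The full redundant condition lists (7 gains, 6 lags, 4 shunted lags,
    8 gain-drop profiles; 25 entries)."""
    conds: list[ReafferenceCondition] = []
    conds += [ReafferenceCondition.of_gain(g) for g in GAIN_VALUES]
    conds += [ReafferenceCondition.of_lag(l) for l in LAG_VALUES_MS]
    conds += [ReafferenceCondition.of_lag(l, shunted=True) for l in SHUNTED_LAG_VALUES_MS]
    conds += [ReafferenceCondition.of_profile(p) for p in GAIN_DROP_PROFILES]
    return conds


def _probe_trace(dt: float = DT) -> tuple[np.ndarray, np.ndarray]:
    """Binary bout-shaped probe used for functional equivalence testing.

    One 400 ms bout at 20 mm/s with enough trailing quiet time (400 ms) to
    expose post-offset reafference of lagged conditions.
    """
    n_pre, n_bout, n_post = 40, 80, 80
    v = np.zeros(n_pre + n_bout + n_post)
    b = np.zeros_like(v, dtype=np.int8)
    v[n_pre : n_pre + n_bout] = 20.0
    b[n_pre : n_pre + n_bout] = 1
    return v, b


def enumerate_conditions(dt: float = DT) -> list[ReafferenceCondition]:
    """Unique reafference conditions after deduplicating the redundant lists.

    Two conditions are merged when they induce identical shown-grating
    mappings on a binary bout-shaped probe velocity trace (e.g. gain 0 and
    infinite lag are both open-loop; gain-drop 0011 coincides with the
    150 ms shunted lag).  Returns 18 conditions, first occurrence kept.
    """
    v, b = _probe_trace(dt)
    unique: list[ReafferenceCondition] = []
    seen: dict[bytes, int] = {}
    for cond in redundant_conditions():
        key = apply_reafference(v, b, cond, dt=dt).tobytes()
        if key not in seen:
            seen[key] = len(unique)
            unique.append(cond)
    return unique


def condition_index(conditions: list[ReafferenceCondition] | None = None) -> dict[str, int]:
    """Map condition label -> position in the canonical unique ordering."""
    conds = enumerate_conditions() if conditions is None else conditions
    return {c.label: i for i, c in enumerate(conds)}


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSpec:
    phase: str  # calibration | pre_adaptation | adaptation | post_adaptation
    policy: str  # "fixed" | "uniform18" | "normal_or_openloop"
    condition: ReafferenceCondition = NORMAL


@dataclass
class Protocol:
    """Ordered trial list plus the stimulus geometry of one experiment.

    Every trial is 7.5 s static grating, 15 s forward grating at 10 mm/s,
    then 7.5 s static (30 s total).  Whole-brain imaging sessions start with
    120 s of blank screen and add two 350 ms reverse-motion pulses 5 and
    10 s after each moving period ends.
    """

    variant: str
    group: str
    trials: list[TrialSpec]
    dt: float = DT
    static_s: float = 7.5
    moving_s: float = 15.0
    grating_speed: float = BASE_VELOCITY
    pre_blank_s: float = 0.0
    reverse_pulses: bool = False

    @property
    def trial_duration_s(self) -> float:
        return 2 * self.static_s + self.moving_s

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        return self.pre_blank_s + self.n_trials * self.trial_duration_s

    @property
    def phase_labels(self) -> list[str]:
        return [t.phase for t in self.trials]

    def trial_start_s(self, i: int) -> float:
        return self.pre_blank_s + i * self.trial_duration_s

    def grating_cmd(self) -> np.ndarray:
        """Command grating velocity for the whole session on the dt grid."""
        n = int(round(self.total_duration_s / self.dt))
        cmd = np.zeros(n)
        n_static = int(round(self.static_s / self.dt))
        n_moving = int(round(self.moving_s / self.dt))
        n_trial = int(round(self.trial_duration_s / self.dt))
        n_blank = int(round(self.pre_blank_s / self.dt))
        for i in range(self.n_trials):
            a = n_blank + i * n_trial + n_static
            cmd[a : a + n_moving] = self.grating_speed
            if self.reverse_pulses:
                stop = a + n_moving
                n_pulse = int(round(0.350 / self.dt))
                for delay_s in (5.0, 10.0):
                    p = stop + int(round(delay_s / self.dt))
                    if p < n:
                        cmd[p : min(p + n_pulse, n)] = -self.grating_speed
        return cmd

    def draw_condition(self, trial_idx: int, rng: np.random.Generator) -> ReafferenceCondition:
        """Reafference condition for a bout starting in the given trial."""
        spec = self.trials[trial_idx]
        if spec.policy == "fixed":
            return spec.condition
        if spec.policy == "uniform18":
            conds = _UNIQUE18()
            return conds[rng.integers(len(conds))]
        if spec.policy == "normal_or_openloop":
            return NORMAL if rng.integers(2) == 0 else OPEN_LOOP
        raise ValueError(f"unknown policy {spec.policy!r}")


_UNIQUE18_CACHE: list[ReafferenceCondition] | None = None


def _UNIQUE18() -> list[ReafferenceCondition]:
    global _UNIQUE18_CACHE
    if _UNIQUE18_CACHE is None:
        _UNIQUE18_CACHE = enumerate_conditions()
    return _UNIQUE18_CACHE


_VARIANTS = ("acute_reaction", "long_term_adaptation", "whole_brain_imaging", "pc_imaging")
_GROUPS = ("normal_reafference_control", "lag_trained")

LAG_TRAINING_CONDITION = ReafferenceCondition.of_lag(225.0, shunted=False)


def build_protocol(
    variant: str,
    group: str = "normal_reafference_control",
    n_adaptation: int | None = None,
) -> Protocol:
    """Assemble one of the four experimental protocols.

    Phase trial counts (calibration/pre/adaptation/post):
    acute_reaction 10/10/210/10 with per-bout conditions drawn uniformly
    from the 18 unique conditions during adaptation; long_term_adaptation
    10/10/210/10 with adaptation fixed at 225 ms non-shunted lag for the
    lag-trained group; pc_imaging 10/10/50/50; whole_brain_imaging
    10/10/40/0 preceded by 120 s of blank, with per-bout conditions drawn
    from {normal, open-loop} and reverse pulses in the static periods.

    ``n_adaptation`` overrides the adaptation-phase length for scaled-down
    simulations; the phase structure is unchanged.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown protocol variant {variant!r}")
    if group not in _GROUPS:
        raise ValueError(f"unknown group {group!r}")

    lagged = group == "lag_trained"
    trials: list[TrialSpec] = []
    trials += [TrialSpec("calibration", "fixed", NORMAL)] * 10
    trials += [TrialSpec("pre_adaptation", "fixed", NORMAL)] * 10

    if variant == "acute_reaction":
        n_ad = 210 if n_adaptation is None else n_adaptation
        trials += [TrialSpec("adaptation", "uniform18")] * n_ad
        trials += [TrialSpec("post_adaptation", "fixed", NORMAL)] * 10
        return Protocol(variant, group, trials)

    if variant == "long_term_adaptation":
        n_ad = 210 if n_adaptation is None else n_adaptation
        cond = LAG_TRAINING_CONDITION if lagged else NORMAL
        trials += [TrialSpec("adaptation", "fixed", cond)] * n_ad
        trials += [TrialSpec("post_adaptation", "fixed", NORMAL)] * 10
        return Protocol(variant, group, trials)

    if variant == "pc_imaging":
        n_ad = 50 if n_adaptation is None else n_adaptation
        cond = LAG_TRAINING_CONDITION if lagged else NORMAL
        trials += [TrialSpec("adaptation", "fixed", cond)] * n_ad
        trials += [TrialSpec("post_adaptation", "fixed", NORMAL)] * 50
        return Protocol(variant, group, trials)

    # whole_brain_imaging
    n_ad = 40 if n_adaptation is None else n_adaptation
    trials += [TrialSpec("adaptation", "normal_or_openloop")] * n_ad
    return Protocol(variant, group, trials, pre_blank_s=120.0, reverse_pulses=True)


# ---------------------------------------------------------------------------
# session container and the generic closed-loop driver
# ---------------------------------------------------------------------------

@dataclass
class TailRecording:
    """Raw record of one closed-loop session on a uniform time grid."""

    time: np.ndarray  # s
    tail_angle: np.ndarray  # rad (cumulative sum of 8 segment angles)
    grating_cmd: np.ndarray  # mm/s, command
    grating_shown: np.ndarray  # mm/s, actually presented
    vigor: np.ndarray  # rad
    est_velocity: np.ndarray  # mm/s
    bout_flag: np.ndarray  # 0/1
    multiplier: float = 1.0  # mm/s per rad
    dt: float = DT
    bout_conditions: list[ReafferenceCondition] = field(default_factory=list)
    tail_angle_raw: np.ndarray | None = None  # kept when tail_angle is z-scored

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("tail_angle", "grating_cmd", "grating_shown", "vigor",
                     "est_velocity", "bout_flag"):
            if getattr(self, name).size != n:
                raise ValueError(f"series {name} does not share the time base")
        if n > 1:
            steps = np.diff(self.time)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time base is not uniformly sampled")
        if self.dt <= 0:
            raise ValueError("sampling period must be positive")
        bf = np.asarray(self.bout_flag)
        if not np.isin(bf, (0, 1)).all():
            raise ValueError("bout_flag must be binary")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("time", "tail_angle", "grating_cmd", "grating_shown",
                         "vigor", "est_velocity", "bout_flag"):
                f.create_dataset(name, data=getattr(self, name))
            if self.tail_angle_raw is not None:
                f.create_dataset("tail_angle_raw", data=self.tail_angle_raw)
            f.attrs["sampling_period"] = self.dt
            f.attrs["multiplier"] = self.multiplier
            f.attrs["bout_conditions"] = [c.label for c in self.bout_conditions]

    @classmethod
    def from_hdf5(cls, path) -> "TailRecording":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("time", "tail_angle", "grating_cmd", "grating_shown",
                   "vigor", "est_velocity", "bout_flag")}
            raw = f["tail_angle_raw"][...] if "tail_angle_raw" in f else None
            labels = [s if isinstance(s, str) else s.decode()
                      for s in f.attrs.get("bout_conditions", [])]
            rec = cls(multiplier=float(f.attrs["multiplier"]),
                      dt=float(f.attrs["sampling_period"]),
                      bout_conditions=[_condition_from_label(l) for l in labels],
                      tail_angle_raw=raw, **kw)
        return rec


def _condition_from_label(label: str) -> ReafferenceCondition:
    if label == "normal":
        return NORMAL
    if label == "open_loop":
        return OPEN_LOOP
    kind, _, rest = label.partition("_")
    if kind == "gain":
        return ReafferenceCondition.of_gain(float(rest))
    if kind == "lag":
        ms, _, sh = rest.partition("_")
        return ReafferenceCondition.of_lag(float(ms), shunted=sh == "shunted")
    if kind == "drop":
        return ReafferenceCondition.of_profile(rest)
    raise ValueError(f"unknown condition label {label!r}")


def run_closed_loop_session(
    protocol: Protocol,
    behaver,
    seed: int = 0,
    multiplier: float = 1.0,
) -> TailRecording:
    """Drive a causal behaver through a whole protocol in closed loop.

    ``behaver(i, shown_prev)`` receives the sample index and the grating
    velocity shown on the previous step and must return the current
    estimated swim velocity in mm/s (e.g. a controller emitting 20 mm/s
    while swimming, or a scripted trace that ignores the stimulus).  Bouts
    are detected online at the 2 mm/s threshold and each bout is assigned a
    reafference condition drawn from the protocol's policy for the trial it
    starts in; draws use the seeded generator, so the session is
    deterministic given seed and behaver.
    """
    rng = np.random.default_rng(seed)
    cmd = protocol.grating_cmd()
    n = cmd.size
    dt = protocol.dt

    shown = np.zeros(n)
    est = np.zeros(n)
    bflag = np.zeros(n, dtype=np.int8)
    pad = int(round(0.400 / dt)) + 2  # longest finite lag + margin
    r_sched = np.zeros(n + pad)
    sched_bout = np.full(n + pad, -1, dtype=np.int64)
    bout_end = {}
    bout_conditions: list[ReafferenceCondition] = []
    n_trial = int(round(protocol.trial_duration_s / dt))
    n_blank = int(round(protocol.pre_blank_s / dt))
    seg = int(round(DROP_SEGMENT_S / dt))

    in_bout = False
    cur = -1
    cur_cond = NORMAL
    cur_on = -1
    shown_prev = cmd[0]

    for t in range(n):
        v = float(behaver(t, shown_prev))
        if not np.isfinite(v):
            raise ValueError("behaver emitted a non-finite velocity")
        est[t] = v
        b = v > 2.0
        bflag[t] = 1 if b else 0
        if b and not in_bout:
            cur += 1
            cur_on = t
            trial_idx = min(max((t - n_blank) // n_trial, 0), protocol.n_trials - 1)
            cur_cond = protocol.draw_condition(trial_idx, rng)
            bout_conditions.append(cur_cond)
            in_bout = True
        elif not b and in_bout:
            bout_end[cur] = t
            in_bout = False

        r = 0.0
        if b:
            c = cur_cond
            if c.kind == "gain":
                r = c.gain * v
            elif c.kind == "gain_drop":
                si = (t - cur_on) // seg
                r = v if (si >= 4 or c.profile[si] == "1") else 0.0
            elif c.kind == "lag" and not math.isinf(c.lag_ms):
                k = int(round(c.lag_ms / 1000.0 / dt))
                r_sched[t + k] += v
                sched_bout[t + k] = cur
        rs = r_sched[t]
        if rs != 0.0:
            sb = sched_bout[t]
            c = bout_conditions[sb]
            if c.shunted and sb in bout_end and t >= bout_end[sb]:
                rs = 0.0
            r += rs
        shown[t] = cmd[t] - r
        shown_prev = shown[t]

    time = np.arange(n) * dt
    vigor = est / multiplier if multiplier else np.zeros(n)
    return TailRecording(
        time=time, tail_angle=np.zeros(n), grating_cmd=cmd, grating_shown=shown,
        vigor=vigor, est_velocity=est, bout_flag=bflag,
        multiplier=multiplier, dt=dt, bout_conditions=bout_conditions,
    )
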