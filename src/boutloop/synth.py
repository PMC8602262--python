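"""Synthetic data with ground truth for every pipeline stage.

Three generator families: (1) behavioral sessions — oscillatory tail traces
organized into bouts either by a scripted schedule or by the feedback
controller run in closed loop, passed through the same vigor / calibration /
reafference machinery as real sessions; (2) fluorescence traces — latent
signals (leaky-integrated optic flow, motor-locked transients, trial-
amplitude-modulated bout responses) convolved with the GCaMP6s kernel plus
Gaussian noise and slow sinusoidal drift; (3) volumetric movies containing
soma-sized Gaussian blobs with shared within-blob time courses.

Generators are deterministic given the seed and always emit ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bouts as bouts_mod
from .controller import (
    REFERENCE_PARAMS,
    ControllerParams,
    ModelTrajectory,
    simulate_protocol,
)
from .imaging import RoiTraceSet, gcamp_kernel, leaky_integrate, motor_regressor
from .reafference import (
    DT,
    CalibrationError,
    Protocol,
    TailRecording,
    apply_reafference,
    bout_intervals,
    calibrate_multiplier,
    compute_vigor,
    detect_bouts_online,
)

__all__ = [
    "SynthConfig",
    "RoiSpec",
    "gen_tail_session",
    "gen_adapting_cohort",
    "first_bout_durations",
    "cohort_metrics",
    "gen_fluorescence",
    "gen_volume",
    "barcode_amplitudes",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic-data generators (field defaults are the
    study's conditions where those are stated, order-of-magnitude
    physiological choices otherwise)."""

    # tail rendering
    tail_beat_hz: float = 25.0        # larval tail-beat frequency
    flick_amplitude_rad: float = 0.6  # sine amplitude; flick magnitude ~2x
    envelope_ramp_ms: float = 30.0    # bout rise/fall time
    tail_noise_sd_rad: float = 0.01   # tracking jitter, below flick threshold

    # scripted bout schedule
    bout_ms: float = 350.0
    bout_sd_ms: float = 60.0
    interbout_ms: float = 800.0
    interbout_sd_ms: float = 200.0
    first_latency_ms: float = 500.0
    first_latency_sd_ms: float = 100.0

    # adapting-cohort schedule
    param_jitter_sd: float = 0.05     # lognormal inter-fish variability
    adaptation_drift: float = 0.6     # fractional omega_i increase when adapting
    nonadapting_blunt: float = 0.8    # omega_r factor in non-adapting fish

    # fluorescence rendering
    drift_amp: float = 0.5            # in units of signal SD
    drift_period_s: float = 600.0     # slow enough for 3.3 mHz detrending
    indicator_half_decay_s: float = 1.8

    # volume rendering
    volume_shape: tuple[int, int, int, int] = (120, 1, 48, 48)  # (T, Z, Y, X)
    voxel_size_um: tuple[float, float, float] = (0.6, 0.6, 7.0)
    blob_sigma_um: float = 1.2
    blob_mask_level: float = 0.3      # mask = profile above this fraction of peak
    min_blob_separation_um: float = 6.0
    blob_snr: float = 5.0


@dataclass(frozen=True)
class RoiSpec:
    """Ground-truth identity of one synthetic ROI."""

    kind: str                 # sensor | integrator | motor | barcode | noise
    tau_s: float | None = None
    profile: str | None = None  # 4-char barcode over {+,0,-}
    snr: float = 10.0           # latent-signal SD over noise SD


# ---------------------------------------------------------------------------
# behavioral sessions
# ---------------------------------------------------------------------------

def _scripted_schedule(protocol: Protocol, cfg: SynthConfig,
                       rng: np.random.Generator) -> list[tuple[float, float]]:
    """Bout (onset_s, offset_s) pairs confined to moving-grating periods."""
    sched = []
    for i in range(protocol.n_trials):
        t_move = protocol.trial_start_s(i) + protocol.static_s
        t_stop = t_move + protocol.moving_s
        t = t_move + max(rng.normal(cfg.first_latency_ms, cfg.first_latency_sd_ms),
                         100.0) / 1000.0
        while True:
            dur = max(rng.normal(cfg.bout_ms, cfg.bout_sd_ms), 120.0) / 1000.0
            if t + dur >= t_stop:
                break
            sched.append((t, t + dur))
            gap = max(rng.normal(cfg.interbout_ms, cfg.interbout_sd_ms), 150.0) / 1000.0
            t += dur + gap
    return sched


def _render_tail(n: int, dt: float, schedule, cfg: SynthConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated tail-beat oscillations over the bout schedule."""
    tail = rng.normal(0.0, cfg.tail_noise_sd_rad, n) if cfg.tail_noise_sd_rad > 0 \
        else np.zeros(n)
    ramp = int(round(cfg.envelope_ramp_ms / 1000.0 / dt))
    for on_s, off_s in schedule:
        a = int(round(on_s / dt))
        z = min(int(round(off_s / dt)), n)
        if z <= a:
            continue
        m = z - a
        t = np.arange(m) * dt
        env = np.ones(m)
        r = min(ramp, m // 2)
        if r > 0:
            env[:r] = np.linspace(0.0, 1.0, r, endpoint=False)
            env[m - r:] = np.linspace(1.0, 0.0, r + 1)[1:]
        # cosine phase: the deflection starts at an extremum, so the first
        # tail flick begins at the true bout onset
        tail[a:z] += cfg.flick_amplitude_rad * env * np.cos(
            2 * np.pi * cfg.tail_beat_hz * t)
    return tail


def gen_tail_session(
    protocol: Protocol,
    config: SynthConfig | None = None,
    seed: int = 0,
    behaver: str | ControllerParams | np.ndarray = "scripted",
) -> tuple[TailRecording, pd.DataFrame]:
    """Closed-loop session with rendered tail kinematics and ground truth.

    Bout timing comes from the behaver: either a scripted schedule
    (stimulus-independent, bouts of ~350 ms during moving-grating periods)
    or the feedback controller run in closed loop (``behaver`` is a
    parameter set or per-trial parameter matrix).  Tail kinematics are
    rendered as enveloped tail-beat oscillations, vigor is computed, the
    vigor-to-velocity multiplier is calibrated on calibration-phase bouts so
    the median in-bout estimated velocity is 20 mm/s, bouts are re-detected
    online at 2 mm/s, and each detected bout receives a reafference
    condition from the protocol policy.  Returns the recording and a
    ground-truth bout table.
    """
    cfg = SynthConfig() if config is None else config
    rng = np.random.default_rng(seed)
    dt = protocol.dt
    cmd = protocol.grating_cmd()
    n = cmd.size

    if isinstance(behaver, str) and behaver == "scripted":
        schedule = _scripted_schedule(protocol, cfg, rng)
        shown_from_model = None
    else:
        traj = simulate_protocol(behaver, protocol, seed=seed)
        schedule = [(on * dt, off * dt) for on, off in
                    zip(traj.onsets, traj.offsets) if off > 0]
        shown_from_model = traj.grating_shown

    tail = _render_tail(n, dt, schedule, cfg, rng)
    vigor = compute_vigor(tail, dt)

    gt_flag = np.zeros(n, dtype=np.int8)
    for on_s, off_s in schedule:
        gt_flag[int(round(on_s / dt)) : int(round(off_s / dt))] = 1

    # calibrate on calibration-phase ground-truth bouts; fall back to the
    # whole session when that phase has none
    n_cal_end = int(round((protocol.pre_blank_s + 10 * protocol.trial_duration_s) / dt))
    cal_mask = gt_flag.astype(bool).copy()
    cal_mask[min(n_cal_end, n):] = False
    try:
        mult = calibrate_multiplier(vigor, cal_mask)
    except CalibrationError:
        mult = calibrate_multiplier(vigor, gt_flag)
    est = vigor * mult
    bout_flag = detect_bouts_online(est)

    # assign a condition to every detected bout and build the shown grating
    conds = []
    r_total = np.zeros(n)
    n_blank = int(round(protocol.pre_blank_s / dt))
    n_trial = int(round(protocol.trial_duration_s / dt))
    for on, off in bout_intervals(bout_flag):
        trial = int(np.clip((on - n_blank) // n_trial, 0, protocol.n_trials - 1))
        cond = protocol.draw_condition(trial, rng)
        conds.append(cond)
        single = np.zeros(n, dtype=np.int8)
        single[on:off] = 1
        r_total += -apply_reafference(est, single, cond, base_velocity=0.0, dt=dt)
    shown = (cmd - r_total) if shown_from_model is None else shown_from_model

    rec = TailRecording(
        time=np.arange(n) * dt, tail_angle=tail, grating_cmd=cmd,
        grating_shown=shown, vigor=vigor, est_velocity=est,
        bout_flag=bout_flag, multiplier=mult, dt=dt, bout_conditions=conds,
    )
    truth = pd.DataFrame(
        [(on_s, off_s, (off_s - on_s) * 1000.0) for on_s, off_s in schedule],
        columns=["onset_s", "offset_s", "duration_ms"],
    )
    return rec, truth


# ---------------------------------------------------------------------------
# adapting cohort
# ---------------------------------------------------------------------------

def first_bout_durations(bout_table: pd.DataFrame, n_trials: int) -> np.ndarray:
    """Per-trial first-bout duration (ms); NaN for trials without one."""
    out = np.full(n_trials, np.nan)
    firsts = bout_table[bout_table["is_first_in_trial"]]
    for t, d in zip(firsts["trial_id"], firsts["duration_ms"]):
        if 0 <= t < n_trials:
            out[int(t)] = d
    return out


def _jittered(params: ControllerParams, rng, sd: float) -> np.ndarray:
    return params.to_array() * np.exp(rng.normal(0.0, sd, 8))


def gen_adapting_cohort(
    n_per_group: int = 20,
    config: SynthConfig | None = None,
    seed: int = 0,
    base_params: ControllerParams = REFERENCE_PARAMS,
    n_adaptation: int | None = None,
) -> list[dict]:
    """Simulated long-term-adaptation cohort for three groups.

    *Control* fish run the normal-reafference protocol with fixed
    parameters.  *Lag-trained adapting* fish run the 225 ms-lag protocol
    while their tiredness-inhibition weight ramps up across the adaptation
    phase (and stays elevated afterwards), emulating recalibration of the
    controller by an internal model; *lag-trained non-adapting* fish keep
    parameters fixed, with slightly blunted reverse-sensor weights.
    Inter-fish variability is lognormal on all eight parameters.

    Returns one record per fish with the per-trial first-bout durations,
    phase labels and adaptation metrics.
    """
    from .reafference import build_protocol

    cfg = SynthConfig() if config is None else config
    rng = np.random.default_rng(seed)
    records = []
    groups = (
        ("control", "normal_reafference_control", False, False),
        ("lag_adapting", "lag_trained", True, False),
        ("lag_nonadapting", "lag_trained", False, True),
    )
    for gname, pgroup, drifts, blunted in groups:
        protocol = build_protocol("long_term_adaptation", pgroup,
                                  n_adaptation=n_adaptation)
        phases = np.asarray(protocol.phase_labels)
        ad_idx = np.flatnonzero(phases == "adaptation")
        for f in range(n_per_group):
            p = _jittered(base_params, rng, cfg.param_jitter_sd)
            if blunted:
                p[1] *= cfg.nonadapting_blunt
            pmat = np.tile(p, (protocol.n_trials, 1))
            if drifts:
                frac = np.linspace(0.0, 1.0, ad_idx.size)
                pmat[ad_idx, 7] = p[7] * (1.0 + cfg.adaptation_drift * frac)
                post = np.flatnonzero(phases == "post_adaptation")
                pmat[post, 7] = p[7] * (1.0 + cfg.adaptation_drift)
            traj = simulate_protocol(pmat, protocol, seed=int(rng.integers(2**31)))
            table = bouts_mod.segment_bouts(traj.as_recording(),
                                            trial_len_s=protocol.trial_duration_s,
                                            flick_correction=False)
            fb = first_bout_durations(table, protocol.n_trials)
            metrics = bouts_mod.adaptation_metrics(fb, phases)
            records.append({
                "group": gname, "fish": f, "first_bout_ms": fb,
                "phases": phases, "metrics": metrics,
            })
    return records


def cohort_metrics(records: list[dict]) -> pd.DataFrame:
    """Tidy per-fish metric table from :func:`gen_adapting_cohort` output."""
    rows = []
    for r in records:
        m = r["metrics"]
        rows.append({
            "group": r["group"], "fish": r["fish"],
            "acute_reaction": m.acute_reaction,
            "reduction": m.reduction_of_acute_reaction,
            "after_effect": m.after_effect,
            "adapting": m.adapting,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def barcode_amplitudes(profile: str, phases: np.ndarray,
                       step: float = 0.6) -> np.ndarray:
    """Per-trial response amplitudes realizing a target ternary barcode.

    Amplitude starts at 1 and steps by +/-``step`` (or holds, for '0') at
    each of the four protocol transitions; the adaptation and post phases
    interpolate between their first-ten and last-ten block levels, so block
    means land on the intended values.
    """
    if len(profile) != 4 or any(c not in "+-0" for c in profile):
        raise ValueError(f"invalid barcode profile {profile!r}")
    d = {"+": step, "-": -step, "0": 0.0}
    a_pre = 1.0
    a_ad_first = a_pre + d[profile[0]]
    a_ad_last = a_ad_first + d[profile[1]]
    a_post_first = a_ad_last + d[profile[2]]
    a_post_last = a_post_first + d[profile[3]]
    phases = np.asarray(phases)
    amp = np.full(phases.size, a_pre)
    ad = np.flatnonzero(phases == "adaptation")
    post = np.flatnonzero(phases == "post_adaptation")
    if ad.size:
        amp[ad] = np.concatenate([
            np.full(min(10, ad.size), a_ad_first),
            np.linspace(a_ad_first, a_ad_last, max(ad.size - 20, 0) + 2)[1:-1],
            np.full(min(10, max(ad.size - 10, 0)), a_ad_last),
        ])[: ad.size]
    if post.size:
        amp[post] = np.concatenate([
            np.full(min(10, post.size), a_post_first),
            np.linspace(a_post_first, a_post_last, max(post.size - 20, 0) + 2)[1:-1],
            np.full(min(10, max(post.size - 10, 0)), a_post_last),
        ])[: post.size]
    return amp


def gen_fluorescence(
    protocol: Protocol,
    session: TailRecording,
    roi_specs: list[RoiSpec],
    fs: float,
    config: SynthConfig | None = None,
    seed: int = 0,
) -> RoiTraceSet:
    """Synthetic ROI fluorescence for one session, with ground truth.

    Latent signals: *sensor*/*integrator* — forward-rectified shown grating
    velocity leaky-integrated at the spec's time constant; *motor* — the
    bout flag; *barcode* — unit impulses at first-bout onsets whose
    amplitude follows the trial schedule realizing the spec's profile;
    *noise* — none.  Latents (except noise) are convolved with the GCaMP6s
    kernel, scaled to unit SD, and contaminated with Gaussian noise of SD
    1/snr plus a slow sinusoidal drift.
    """
    cfg = SynthConfig() if config is None else config
    rng = np.random.default_rng(seed)
    t_frames = np.arange(0.0, protocol.total_duration_s, 1.0 / fs)
    n_f = t_frames.size

    shown_f = np.interp(t_frames, session.time, session.grating_shown)
    # motor latent is built at the session rate (bouts are shorter than one
    # imaging frame) and sampled at frame times afterwards
    fs_session = 1.0 / session.dt
    motor_full = motor_regressor(session.bout_flag.astype(float), fs_session)
    motor_f = np.interp(t_frames, session.time, motor_full)

    # trigger annotations (frame indices)
    grating_onsets = np.array([
        int(round((protocol.trial_start_s(i) + protocol.static_s) * fs))
        for i in range(protocol.n_trials)])
    onsets_s = np.array([on * session.dt for on, _ in bout_intervals(session.bout_flag)])
    bout_onsets = np.unique((onsets_s * fs).astype(int))
    first_bout = np.full(protocol.n_trials, -1, dtype=int)
    for i in range(protocol.n_trials):
        t0 = protocol.trial_start_s(i)
        t1 = t0 + protocol.trial_duration_s
        inside = onsets_s[(onsets_s >= t0) & (onsets_s < t1)]
        if inside.size:
            first_bout[i] = int(round(inside[0] * fs))
    phases = np.asarray(protocol.phase_labels)

    kern = gcamp_kernel(fs, cfg.indicator_half_decay_s)
    traces = np.empty((len(roi_specs), n_f))
    truth_rows = []
    for i, spec in enumerate(roi_specs):
        if spec.kind in ("sensor", "integrator"):
            if spec.tau_s is None:
                raise ValueError("sensor/integrator specs need tau_s")
            x = leaky_integrate(np.clip(shown_f, 0.0, None), spec.tau_s, fs)
            latent = np.convolve(x, kern)[:n_f]
        elif spec.kind == "motor":
            latent = motor_f
        elif spec.kind == "barcode":
            amp = barcode_amplitudes(spec.profile, phases)
            imp = np.zeros(n_f)
            for trial, fr in enumerate(first_bout):
                if fr >= 0:
                    imp[fr] = amp[trial]
            latent = np.convolve(imp, kern)[:n_f]
        elif spec.kind == "noise":
            latent = np.zeros(n_f)
        else:
            raise ValueError(f"unknown ROI kind {spec.kind!r}")
        sd = latent.std()
        if sd > 0:
            latent = latent / sd
        noise_sd = 1.0 / spec.snr
        drift = cfg.drift_amp * np.sin(
            2 * np.pi * t_frames / cfg.drift_period_s + rng.uniform(0, 2 * np.pi))
        traces[i] = latent + rng.normal(0.0, noise_sd, n_f) + drift
        truth_rows.append({"roi": i, "kind": spec.kind, "tau_s": spec.tau_s,
                           "profile": spec.profile, "snr": spec.snr})

    return RoiTraceSet(
        traces=traces, fs=fs, grating_onsets=grating_onsets,
        bout_onsets=bout_onsets, first_bout_onsets=first_bout,
        trial_phase=phases, ground_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# volumetric movies
# ---------------------------------------------------------------------------

def gen_volume(
    n_blobs: int,
    config: SynthConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Noisy movie containing soma-sized blobs with shared time courses.

    Blobs have Gaussian spatial profiles (sigma ~1.2 um); the ground-truth
    mask is the region above 30% of the peak, whose area falls inside the
    9-28 um^2 soma bounds at the 0.6 um voxel size.  Every voxel of a blob
    shares that blob's smooth positive time course, scaled by the spatial
    profile; background is white Gaussian noise with SD = 1/snr of the blob
    time-course SD.  Returns ``(movie (T,Z,Y,X), masks, blob_traces)``.
    """
    cfg = SynthConfig() if config is None else config
    rng = np.random.default_rng(seed)
    T, Z, Y, X = cfg.volume_shape
    dy, dx = cfg.voxel_size_um[1], cfg.voxel_size_um[0]
    sig_y = cfg.blob_sigma_um / dy
    sig_x = cfg.blob_sigma_um / dx
    min_sep = cfg.min_blob_separation_um

    # rejection-sample well-separated centers
    centers = []
    margin = int(np.ceil(3 * max(sig_y, sig_x))) + 1
    attempts = 0
    while len(centers) < n_blobs:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("cannot place blobs without exceeding the overlap limit")
        z = int(rng.integers(Z))
        y = float(rng.uniform(margin, Y - margin))
        x = float(rng.uniform(margin, X - margin))
        ok = all(cz != z or np.hypot((cy - y) * dy, (cx - x) * dx) >= min_sep
                 for cz, cy, cx in centers)
        if ok:
            centers.append((z, y, x))

    movie = np.zeros((T, Z, Y, X))
    masks = []
    blob_traces = np.empty((n_blobs, T))
    yy, xx = np.mgrid[0:Y, 0:X]
    for k, (z, cy, cx) in enumerate(centers):
        prof = np.exp(-0.5 * (((yy - cy) / sig_y) ** 2 + ((xx - cx) / sig_x) ** 2))
        mask3 = np.zeros((Z, Y, X), dtype=bool)
        mask3[z] = prof >= cfg.blob_mask_level
        masks.append(mask3)
        # smooth positive time course: sparse events through the indicator
        events = (rng.random(T) < 0.08).astype(float) * rng.uniform(0.5, 1.5, T)
        tr = np.convolve(events, gcamp_kernel(1.5, cfg.indicator_half_decay_s))[:T]
        blob_traces[k] = tr
        movie[:, z] += tr[:, None, None] * prof[None, :, :]

    sd_ref = blob_traces.std(axis=1).mean() if n_blobs else 1.0
    movie += rng.normal(0.0, sd_ref / cfg.blob_snr, movie.shape)
    return movie, masks, blob_traces
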