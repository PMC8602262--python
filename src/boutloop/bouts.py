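"""Offline behavioral analysis of closed-loop sessions.

The raw tail trace is resampled to a 5 ms grid and z-scored; bouts detected
online by the velocity threshold are refined by snapping their boundaries to
individual *tail flicks* (sections between adjacent local extrema with
magnitude > 0.14 rad and duration <= 100 ms).  Bouts outside forward-grating
periods, bouts shorter than 100 ms and bouts flanked by interbouts shorter
than 100 ms are excluded.  Per-bout power profiles (squared baseline-
subtracted tail angle over -100 ms .. +1000 ms around onset) are split at
220 ms post-onset into a ballistic and a reactive area.  Long-term
adaptation is quantified by block-of-ten first-bout-duration differences:
acute reaction, reduction of acute reaction, and after-effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reafference import DT, TailRecording, bout_intervals

__all__ = [
    "FLICK_MAGNITUDE_RAD",
    "FLICK_MAX_DURATION_MS",
    "MIN_BOUT_MS",
    "MIN_INTERBOUT_MS",
    "POWER_N_SAMPLES",
    "AdaptationMetrics",
    "preprocess_tail",
    "local_extrema",
    "detect_flicks",
    "segment_bouts",
    "exclude_fish",
    "bout_power",
    "split_power",
    "adaptation_metrics",
    "timepoint_condition_test",
    "group_compare",
]

FLICK_MAGNITUDE_RAD = 0.14
FLICK_MAX_DURATION_MS = 100.0
MIN_BOUT_MS = 100.0
MIN_INTERBOUT_MS = 100.0

#: bout-power window: [-100 ms, +1000 ms) around onset at 5 ms -> 220 samples
POWER_PRE_S = 0.100
POWER_POST_S = 1.000
POWER_N_SAMPLES = 220

#: ballistic/reactive boundary after bout onset (s)
BALLISTIC_S = 0.220

ADAPTING_THRESHOLD_MS = 40.0


def preprocess_tail(raw: TailRecording, dt: float = DT) -> TailRecording:
    """Resample to the 5 ms grid and z-score the tail trace.

    Grating and velocity series are linearly interpolated to the same grid;
    the bout flag is carried over by nearest-previous sample.  The raw
    (radian) tail trace is preserved in ``tail_angle_raw`` because bout
    power is measured in squared radians.
    """
    t_old = raw.time
    if not np.all(np.isfinite(raw.tail_angle)):
        raise ValueError("tail trace contains non-finite samples")
    t_new = np.arange(t_old[0], t_old[-1] + dt / 2, dt)

    def interp(y):
        return np.interp(t_new, t_old, np.asarray(y, dtype=float))

    tail = interp(raw.tail_angle)
    sd = tail.std()
    if sd == 0:
        raise ValueError("constant tail trace: z-score undefined")
    tail_z = (tail - tail.mean()) / sd
    # nearest-previous for the binary flag
    idx = np.searchsorted(t_old, t_new, side="right") - 1
    bout = np.asarray(raw.bout_flag)[np.clip(idx, 0, t_old.size - 1)]
    return TailRecording(
        time=t_new, tail_angle=tail_z, grating_cmd=interp(raw.grating_cmd),
        grating_shown=interp(raw.grating_shown), vigor=interp(raw.vigor),
        est_velocity=interp(raw.est_velocity), bout_flag=bout.astype(np.int8),
        multiplier=raw.multiplier, dt=dt, bout_conditions=raw.bout_conditions,
        tail_angle_raw=tail,
    )


def local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of local extrema; plateaus contribute their first sample."""
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    # propagate the sign of the last non-zero step across plateaus
    s = np.sign(d)
    last = 0.0
    for i in range(s.size):
        if s[i] == 0.0:
            s[i] = last
        else:
            last = s[i]
    turns = np.flatnonzero(s[1:] * s[:-1] < 0) + 1
    # shift each turning point back to the first sample of its plateau
    out = []
    for i in turns:
        j = i
        while j > 0 and x[j - 1] == x[j]:
            j -= 1
        out.append(j)
    return np.unique(out)


def detect_flicks(tail: np.ndarray, dt: float = DT) -> pd.DataFrame:
    """Tail flicks: sections between adjacent local extrema.

    A qualifying flick has magnitude (|angle difference between its two
    bounding extrema|) greater than 0.14 rad and duration not greater than
    100 ms.  Returns a frame with columns start, stop (sample indices of the
    bounding extrema) and magnitude.
    """
    ext = local_extrema(tail)
    if ext.size < 2:
        return pd.DataFrame(columns=["start", "stop", "magnitude"])
    start = ext[:-1]
    stop = ext[1:]
    mag = np.abs(tail[stop] - tail[start])
    dur_ms = (stop - start) * dt * 1000.0
    keep = (mag > FLICK_MAGNITUDE_RAD) & (dur_ms <= FLICK_MAX_DURATION_MS)
    return pd.DataFrame({"start": start[keep], "stop": stop[keep],
                         "magnitude": mag[keep]})


def _trial_of(time_s, trial_len_s: float, t0: float):
    return np.floor((time_s - t0) / trial_len_s).astype(int)


def segment_bouts(
    rec: TailRecording,
    trial_len_s: float = 30.0,
    t0: float = 0.0,
    flick_correction: bool = True,
) -> pd.DataFrame:
    """Refined bout table from a preprocessed recording.

    Online bout-flag intervals are snapped to the first/last qualifying tail
    flick overlapping them; intervals with no qualifying flick are dropped.
    Pass ``flick_correction=False`` for binary-model recordings that have no
    tail kinematics.  Bouts must start while the grating moves forward;
    bouts shorter than 100 ms, or flanked by an interbout shorter than
    100 ms, are excluded.  The subsequent interbout of the last bout in a
    trial is undefined (NaN).
    """
    dt = rec.dt
    intervals = bout_intervals(rec.bout_flag)
    flicks = detect_flicks(rec.tail_angle, dt) if flick_correction else None

    rows = []
    for bi, (on, off) in enumerate(intervals):
        if flick_correction:
            f = flicks[(flicks["stop"] > on) & (flicks["start"] < off)]
            if f.empty:
                continue
            on_c = int(f["start"].iloc[0])
            off_c = int(f["stop"].iloc[-1])
        else:
            on_c, off_c = on, off
        cond = (rec.bout_conditions[bi].label
                if bi < len(rec.bout_conditions) else None)
        rows.append((on_c, off_c, cond))
    if not rows:
        return _empty_bout_table()

    df = pd.DataFrame(rows, columns=["onset_idx", "offset_idx", "condition"])
    df = df.sort_values("onset_idx").reset_index(drop=True)
    df["onset_s"] = df["onset_idx"] * dt + rec.time[0]
    df["offset_s"] = df["offset_idx"] * dt + rec.time[0]
    df["duration_ms"] = (df["offset_idx"] - df["onset_idx"]) * dt * 1000.0

    # bouts must occur while the grating moves forward
    fwd = rec.grating_cmd[df["onset_idx"].to_numpy()] > 0
    df = df[fwd].reset_index(drop=True)
    if df.empty:
        return _empty_bout_table()

    # interbouts between consecutive surviving bouts
    prev_ib = np.full(len(df), np.inf)
    next_ib = np.full(len(df), np.inf)
    gaps = (df["onset_idx"].to_numpy()[1:] - df["offset_idx"].to_numpy()[:-1]) * dt * 1e3
    prev_ib[1:] = gaps
    next_ib[:-1] = gaps

    keep = (
        (df["duration_ms"].to_numpy() >= MIN_BOUT_MS)
        & (prev_ib >= MIN_INTERBOUT_MS)
        & (next_ib >= MIN_INTERBOUT_MS)
    )
    df = df[keep].reset_index(drop=True)
    next_ib = next_ib[keep]
    if df.empty:
        return _empty_bout_table()

    df["trial_id"] = _trial_of(df["onset_s"].to_numpy(), trial_len_s, t0)
    df["is_first_in_trial"] = ~df["trial_id"].duplicated()
    # interbout undefined for the last bout of each trial
    same_trial_next = np.zeros(len(df), dtype=bool)
    same_trial_next[:-1] = df["trial_id"].to_numpy()[1:] == df["trial_id"].to_numpy()[:-1]
    df["next_interbout_ms"] = np.where(same_trial_next, next_ib, np.nan)
    return df


def _empty_bout_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "onset_idx", "offset_idx", "condition", "onset_s", "offset_s",
        "duration_ms", "trial_id", "is_first_in_trial", "next_interbout_ms"])


def exclude_fish(trial_bout_counts) -> bool:
    """Keep the animal unless some 10 consecutive trials contain no bouts."""
    run = 0
    for c in trial_bout_counts:
        run = run + 1 if c == 0 else 0
        if run >= 10:
            return False
    return True


def bout_power(rec: TailRecording, bouts: pd.DataFrame,
               use_zscored: bool = False) -> np.ndarray:
    """Per-bout power profiles (rad^2), shape (n_bouts, 220).

    A 1.1 s tail-trace section starting 100 ms before onset is taken from
    the raw radian trace (or the z-scored one when ``use_zscored``), samples
    after the bout offset are zeroed, the median of the 100 ms pre-onset
    baseline is subtracted, and the section is squared.  Bouts too close to
    the recording boundaries yield all-NaN rows.
    """
    tail = rec.tail_angle if (use_zscored or rec.tail_angle_raw is None) \
        else rec.tail_angle_raw
    dt = rec.dt
    n_pre = int(round(POWER_PRE_S / dt))
    n_tot = POWER_N_SAMPLES
    out = np.full((len(bouts), n_tot), np.nan)
    for k, row in enumerate(bouts.itertuples()):
        on = int(row.onset_idx)
        off = int(row.offset_idx)
        a = on - n_pre
        if a < 0 or a + n_tot > tail.size:
            continue
        seg = tail[a : a + n_tot] - np.median(tail[a:on])
        rel_off = off - a
        if rel_off < n_tot:
            # movement is absent after the offset: zeroed, not baseline-shifted
            seg = seg.copy()
            seg[rel_off:] = 0.0
        out[k] = seg ** 2
    return out


def split_power(profile: np.ndarray, dt: float = DT) -> tuple[float, float]:
    """Trapezoidal areas of a power profile over the ballistic period
    (0-220 ms post-onset) and the reactive period (220-1000 ms)."""
    profile = np.asarray(profile, dtype=float)
    n_pre = int(round(POWER_PRE_S / dt))
    n_bal = int(round(BALLISTIC_S / dt))
    t = (np.arange(profile.size) - n_pre) * dt
    b0, b1 = n_pre, n_pre + n_bal
    ballistic = float(np.trapezoid(profile[b0 : b1 + 1], t[b0 : b1 + 1]))
    reactive = float(np.trapezoid(profile[b1:], t[b1:]))
    return ballistic, reactive


@dataclass
class AdaptationMetrics:
    """Block-of-ten differences of a per-trial behavioral parameter."""

    acute_reaction: float               # first 10 adaptation - pre-adaptation
    reduction_of_acute_reaction: float  # last 10 - first 10 adaptation
    after_effect: float                 # post-adaptation - pre-adaptation
    adapting: bool                      # reduction <= -40 ms rule


def _block_mean(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    return float(v.mean()) if v.size else np.nan


def adaptation_metrics(values_per_trial, phases,
                       adapting_threshold: float = ADAPTING_THRESHOLD_MS
                       ) -> AdaptationMetrics:
    """Acute reaction, its reduction, and the after-effect.

    ``values_per_trial`` holds one value per trial (NaN when the trial has
    no first bout); trials without a value are skipped inside each block.
    The animal counts as adapting when the last-ten-adaptation mean is below
    the first-ten mean by at least 40 ms (meaningful for first-bout
    durations; the power analogues use the same block structure).
    """
    values = np.asarray(values_per_trial, dtype=float)
    phases = np.asarray(phases)
    if values.size != phases.size:
        raise ValueError("one value per trial required")
    pre = values[phases == "pre_adaptation"]
    ad = values[phases == "adaptation"]
    post = values[phases == "post_adaptation"]
    if ad.size < 20:
        raise ValueError("adaptation phase must contain at least two blocks of ten")
    m_pre = _block_mean(pre)
    m_ad_first = _block_mean(ad[:10])
    m_ad_last = _block_mean(ad[-10:])
    m_post = _block_mean(post[:10])
    acute = m_ad_first - m_pre
    reduction = m_ad_last - m_ad_first
    after = m_post - m_pre
    adapting = bool(reduction <= -adapting_threshold) if np.isfinite(reduction) else False
    return AdaptationMetrics(acute, reduction, after, adapting)


def timepoint_condition_test(profiles_by_condition: dict[str, np.ndarray],
                             alpha: float = 0.05,
                             n_tests: int = POWER_N_SAMPLES
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint Kruskal-Wallis across reafference conditions.

    Returns ``(significant_mask, p_values)`` with the Bonferroni threshold
    alpha / n_tests.  Timepoints where some group has no defined value are
    masked out (NaN p).
    """
    groups = list(profiles_by_condition.values())
    if len(groups) < 2:
        raise ValueError("need at least two condition groups")
    n_t = groups[0].shape[1]
    pvals = np.full(n_t, np.nan)
    for j in range(n_t):
        samples = []
        ok = True
        for g in groups:
            col = g[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                ok = False
                break
            samples.append(col)
        if not ok:
            continue
        try:
            pvals[j] = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical in every group
            pvals[j] = 1.0
    mask = pvals < alpha / n_tests
    return mask, pvals


def group_compare(x, y, alternative: str = "two-sided") -> float:
    """Mann-Whitney U rank test between two groups of per-fish metrics.

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's policy).  Fully
    tied data yield p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values tied across groups; rank test degenerate")
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)
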