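"""Calcium-imaging analysis: traces, time constants, ROIs, barcodes.

Covers the two imaging arms of the pipeline.  For whole-brain recordings
(~1.5 Hz volumetric sampling): Butterworth denoising and drift removal,
grating- and bout-triggered averages, shuffle-null sensory/motor scores,
leaky-integrator time-constant estimation (sensor vs integrator boundary at
1.5 s), correlation-map ROI segmentation, and adaptation-related
time-constant changes.  For Purkinje-cell recordings (~4-5 Hz): high-pass
drift removal, a motor regressor (bout flag convolved with a GCaMP6s
kernel), first-bout-triggered responses, the four protocol-transition
criteria, and their conversion to ternary response barcodes via a trial-
shuffling null, with per-cluster enrichment statistics across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "GCAMP6S_HALF_DECAY_S",
    "gcamp_kernel",
    "preprocess_trace",
    "triggered_average",
    "sensory_motor_scores",
    "leaky_integrate",
    "fit_time_constant",
    "TAU_GRID_S",
    "SENSOR_TAU_MAX_S",
    "tau_change",
    "segment_rois",
    "motor_regressor",
    "compute_criteria",
    "barcode",
    "cluster_enrichment",
    "RoiTraceSet",
]

#: GCaMP6s impulse response: exponential with 1.8 s half-decay.
GCAMP6S_HALF_DECAY_S = 1.8

#: time-constant search grid (s) and the sensor/integrator boundary.
TAU_GRID_S = np.arange(0.5, 10.0 + 1e-9, 0.5)
SENSOR_TAU_MAX_S = 1.5

#: Butterworth cutoffs (Hz): denoising low-pass and drift baseline.
LOWPASS_HZ = 0.56
DRIFT_HZ = 3.3e-3

#: section length for the circular-structure-preserving shuffle null (s).
SHUFFLE_SECTION_S = 23.0


def gcamp_kernel(fs: float, half_decay_s: float = GCAMP6S_HALF_DECAY_S,
                 n_taus: float = 8.0) -> np.ndarray:
    """Sampled causal indicator kernel exp(-t / tau), tau = half_decay/ln 2."""
    tau = half_decay_s / np.log(2.0)
    n = max(2, int(round(n_taus * tau * fs)))
    t = np.arange(n) / fs
    return np.exp(-t / tau)


def _butter_sos(cutoff_hz: float, fs: float, btype: str):
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    return signal.butter(4, cutoff_hz, btype=btype, fs=fs, output="sos")


def preprocess_trace(raw: np.ndarray, fs: float, mode: str = "whole_brain") -> np.ndarray:
    """Filter and z-score one fluorescence trace.

    ``whole_brain``: 0.56 Hz low-pass (indicator-bandwidth denoising), then
    subtraction of a 3.3 mHz low-pass baseline (slow drift), then z-score.
    ``pc``: 3.3 mHz high-pass, then z-score.  Filters are zero-phase
    (forward-backward) order-4 Butterworth.
    """
    x = np.asarray(raw, dtype=float)
    if x.std() == 0:
        raise ValueError("constant trace cannot be z-scored")
    if mode == "whole_brain":
        x = signal.sosfiltfilt(_butter_sos(LOWPASS_HZ, fs, "lowpass"), x)
        baseline = signal.sosfiltfilt(_butter_sos(DRIFT_HZ, fs, "lowpass"), x)
        x = x - baseline
    elif mode == "pc":
        x = signal.sosfiltfilt(_butter_sos(DRIFT_HZ, fs, "highpass"), x)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant trace cannot be z-scored")
    return (x - x.mean()) / sd


def triggered_average(
    trace: np.ndarray,
    triggers: np.ndarray,
    fs: float,
    pre_s: float = 1.0,
    post_s: float = 4.0,
    all_triggers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-subtracted trigger-aligned mean, SEM and per-trigger matrix.

    Windows span ``[-pre_s, post_s)`` around each trigger.  Triggers with
    another trigger in the preceding second are dropped; samples after a
    subsequent trigger inside the window are NaN-masked; the pre-trigger
    mean is subtracted per window.  ``all_triggers`` lets bout triggers be
    masked against grating triggers and vice versa; by default only the
    provided trigger train masks itself.
    """
    trace = np.asarray(trace, dtype=float)
    trig = np.asarray(triggers, dtype=int)
    others = trig if all_triggers is None else np.asarray(all_triggers, dtype=int)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_win = n_pre + n_post
    n_lockout = int(round(1.0 * fs))

    windows = []
    for t0 in trig:
        if t0 - n_pre < 0 or t0 + n_post > trace.size:
            continue
        prev = others[(others < t0) & (others >= t0 - n_lockout)]
        if prev.size:
            continue
        w = trace[t0 - n_pre : t0 + n_post].copy()
        nxt = others[(others > t0) & (others < t0 + n_post)]
        if nxt.size:
            w[n_pre + (nxt.min() - t0):] = np.nan
        w -= np.nanmean(w[:n_pre])
        windows.append(w)
    if not windows:
        raise ValueError("no admissible triggers in the recording")
    mat = np.vstack(windows)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tails
        mean = np.nanmean(mat, axis=0)
        n_eff = np.sum(~np.isnan(mat), axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return mean, sem, mat


def _score(trace, triggers, fs, post_score_s, all_triggers=None):
    """Mean of the average triggered fluorescence within [0, post_score_s]."""
    mean, _, _ = triggered_average(trace, triggers, fs, pre_s=1.0, post_s=4.0,
                                   all_triggers=all_triggers)
    n_pre = int(round(1.0 * fs))
    n_sc = int(round(post_score_s * fs))
    return float(np.nanmean(mean[n_pre : n_pre + n_sc]))


def sensory_motor_scores(
    trace: np.ndarray,
    grating_onsets: np.ndarray,
    bout_onsets: np.ndarray,
    fs: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    section_s: float = SHUFFLE_SECTION_S,
) -> dict:
    """Sensory/motor scores with a section-shuffle null classification.

    The sensory score is the mean grating-triggered fluorescence 0-4 s after
    grating onsets; the motor score the mean bout-triggered fluorescence
    0-2 s after bout onsets.  The null divides the trace into 23 s sections,
    permutes them ``n_shuffles`` times and recomputes both scores; a score
    above the 95th percentile of its null is significant.  An ROI is
    *sensory* if its sensory score is significant, *motor* if only the motor
    score is, and *unclassified* otherwise.
    """
    trace = np.asarray(trace, dtype=float)
    rng = np.random.default_rng(seed)
    sec_n = int(round(section_s * fs))
    n_sec = trace.size // sec_n
    if n_sec < 2:
        raise ValueError("trace too short to build the section-shuffle null")

    s_obs = _score(trace, grating_onsets, fs, 4.0)
    m_obs = _score(trace, bout_onsets, fs, 2.0)

    head = trace[: n_sec * sec_n].reshape(n_sec, sec_n)
    tail = trace[n_sec * sec_n:]
    null_s = np.empty(n_shuffles)
    null_m = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(n_sec)
        shuffled = np.concatenate([head[perm].ravel(), tail])
        null_s[i] = _score(shuffled, grating_onsets, fs, 4.0)
        null_m[i] = _score(shuffled, bout_onsets, fs, 2.0)

    s_sig = s_obs > np.percentile(null_s, 95)
    m_sig = m_obs > np.percentile(null_m, 95)
    label = "sensory" if s_sig else ("motor" if m_sig else "unclassified")
    return {
        "sensory_score": s_obs,
        "motor_score": m_obs,
        "sensory_significant": bool(s_sig),
        "motor_significant": bool(m_sig),
        "class": label,
    }


def leaky_integrate(u: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """Exponential-Euler leaky integration x' = (-x + u) / tau."""
    a = np.exp(-1.0 / (tau_s * fs))
    # single-pole IIR: x[t] = a x[t-1] + (1-a) u[t]
    return signal.lfilter([1.0 - a], [1.0, -a], np.asarray(u, dtype=float))


def fit_time_constant(
    trace: np.ndarray,
    stimulus: np.ndarray,
    fs: float,
    taus: np.ndarray = TAU_GRID_S,
    rectify_forward: bool = True,
    preprocess_mode: str | None = None,
) -> tuple[float, float, str]:
    """Best leaky-integrator time constant for a sensory ROI.

    The stimulus velocity (forward-rectified by default) is leaky-integrated
    at each candidate tau on the 0.5-10 s grid, convolved with the GCaMP6s
    kernel and correlated with the trace; the argmax-correlation tau wins.
    When the trace went through :func:`preprocess_trace`, pass the same
    ``preprocess_mode`` so the candidate regressors receive identical
    filtering — an unfiltered regressor against a filtered trace biases the
    estimate toward short time constants.  Returns ``(tau, correlation,
    label)`` where the label is ``sensor`` for tau <= 1.5 s and
    ``integrator`` otherwise.
    """
    trace = np.asarray(trace, dtype=float)
    if np.std(trace) == 0:
        raise ValueError("constant trace: correlation undefined")
    u = np.asarray(stimulus, dtype=float)
    if rectify_forward:
        u = np.clip(u, 0.0, None)
    kern = gcamp_kernel(fs)
    best_tau, best_r = np.nan, -np.inf
    for tau in np.asarray(taus, dtype=float):
        x = leaky_integrate(u, tau, fs)
        y = np.convolve(x, kern)[: x.size]
        if np.std(y) == 0:
            continue
        if preprocess_mode is not None:
            y = preprocess_trace(y, fs, preprocess_mode)
        r = float(np.corrcoef(trace, y)[0, 1])
        if r > best_r:
            best_tau, best_r = tau, r
    label = "sensor" if best_tau <= SENSOR_TAU_MAX_S else "integrator"
    return best_tau, best_r, label


@dataclass
class TauChange:
    delta: np.ndarray          # per-ROI tau(end) - tau(begin), s
    decreased: np.ndarray      # delta < -0.4 s
    grid: np.ndarray           # histogram support, s
    density: np.ndarray        # kernel-smoothed probability density


def tau_change(tau_begin, tau_end, kernel_width_s: float = 0.1,
               decrease_threshold_s: float = 0.4) -> TauChange:
    """Distribution of adaptation-related time-constant changes.

    Pairs with a missing estimate in either block are skipped.  The
    histogram of per-ROI differences is smoothed with a Gaussian kernel of
    width 0.1 s and normalized to unit integral; ROIs whose time constant
    decreased by more than 0.4 s are flagged.
    """
    b = np.asarray(tau_begin, dtype=float)
    e = np.asarray(tau_end, dtype=float)
    ok = ~(np.isnan(b) | np.isnan(e))
    delta = e[ok] - b[ok]
    grid = np.arange(-10.0, 10.0 + 1e-9, 0.05)
    if delta.size:
        dens = np.exp(-0.5 * ((grid[:, None] - delta[None, :]) / kernel_width_s) ** 2).sum(axis=1)
        dens /= np.trapezoid(dens, grid)
    else:
        dens = np.zeros_like(grid)
    return TauChange(delta=delta, decreased=delta < -decrease_threshold_s,
                     grid=grid, density=dens)


# ---------------------------------------------------------------------------
# correlation-map ROI segmentation
# ---------------------------------------------------------------------------

def _correlation_map(plane: np.ndarray) -> np.ndarray:
    """Correlation of each voxel trace with the mean of its 8 in-plane
    neighbors; ``plane`` has shape (T, Y, X)."""
    T, Y, X = plane.shape
    mean = plane.mean(axis=0)
    sd = plane.std(axis=0)
    z = (plane - mean) / np.where(sd == 0, 1.0, sd)
    nbr_sum = np.zeros_like(plane)
    cnt = np.zeros((Y, X))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ys = slice(max(dy, 0), Y + min(dy, 0))
            yd = slice(max(-dy, 0), Y + min(-dy, 0))
            xs = slice(max(dx, 0), X + min(dx, 0))
            xd = slice(max(-dx, 0), X + min(-dx, 0))
            nbr_sum[:, yd, xd] += plane[:, ys, xs]
            cnt[yd, xd] += 1
    nbr = nbr_sum / cnt
    nm = nbr.mean(axis=0)
    nsd = nbr.std(axis=0)
    zn = (nbr - nm) / np.where(nsd == 0, 1.0, nsd)
    corr = (z * zn).mean(axis=0)
    corr[(sd == 0) | (nsd == 0)] = 0.0
    return corr


def segment_rois(
    movie: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (0.6, 0.6, 7.0),
    seed_threshold: float = 0.3,
    grow_threshold: float = 0.3,
    grow_threshold_max: float = 0.35,
    grow_ramp_um: float = 3.0,
    area_bounds_um2: tuple[float, float] = (9.0, 28.0),
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Plane-wise correlation-map ROI segmentation of a volumetric movie.

    ``movie`` has shape (T, Z, Y, X).  Each ROI grows from the unassigned
    voxel with the highest correlation-map value (minimum 0.3): an adjacent
    voxel joins when its correlation with the mean trace of the voxels
    already in the ROI exceeds a threshold ramping linearly from 0.3 at the
    seed to 0.35 at 3 um in-plane distance.  ROIs outside the 9-28 um^2
    soma-area bounds are discarded.  Returns a label volume (Z, Y, X; 0 is
    background) and the per-ROI summed fluorescence traces.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 4:
        raise ValueError("movie must be (T, Z, Y, X)")
    T, Z, Y, X = movie.shape
    if T < 2:
        raise ValueError("movie needs at least two time points")
    dy, dx = voxel_size_um[1], voxel_size_um[0]
    vox_area = dy * dx
    lo_vox = int(np.ceil(area_bounds_um2[0] / vox_area))
    hi_vox = int(np.floor(area_bounds_um2[1] / vox_area))

    labels = np.zeros((Z, Y, X), dtype=np.int32)
    traces: list[np.ndarray] = []
    next_label = 1
    for z in range(Z):
        plane = movie[:, z]
        cmap = _correlation_map(plane)
        assigned = np.zeros((Y, X), dtype=bool)
        while True:
            cand = np.where(assigned, -np.inf, cmap)
            sy, sx = np.unravel_index(np.argmax(cand), cand.shape)
            if cand[sy, sx] < seed_threshold:
                break
            roi = {(sy, sx)}
            assigned[sy, sx] = True
            roi_sum = plane[:, sy, sx].copy()
            rejected: set[tuple[int, int]] = set()
            grew = True
            while grew:
                grew = False
                mean_tr = roi_sum / len(roi)
                msd = mean_tr.std()
                if msd == 0:
                    break
                mz = (mean_tr - mean_tr.mean()) / msd
                frontier = set()
                for (y, x) in roi:
                    for ny in range(max(y - 1, 0), min(y + 2, Y)):
                        for nx in range(max(x - 1, 0), min(x + 2, X)):
                            if (ny, nx) not in roi and (ny, nx) not in rejected \
                                    and not assigned[ny, nx]:
                                frontier.add((ny, nx))
                for (ny, nx) in frontier:
                    v = plane[:, ny, nx]
                    vsd = v.std()
                    if vsd == 0:
                        rejected.add((ny, nx))
                        continue
                    r = float(np.mean((v - v.mean()) / vsd * mz))
                    dist = np.hypot((ny - sy) * dy, (nx - sx) * dx)
                    thr = grow_threshold + (grow_threshold_max - grow_threshold) \
                        * min(dist / grow_ramp_um, 1.0)
                    if r >= thr:
                        roi.add((ny, nx))
                        assigned[ny, nx] = True
                        roi_sum = roi_sum + v
                        grew = True
                    else:
                        rejected.add((ny, nx))
            if lo_vox <= len(roi) <= hi_vox:
                for (y, x) in roi:
                    labels[z, y, x] = next_label
                traces.append(roi_sum)
                next_label += 1
    return labels, traces


# ---------------------------------------------------------------------------
# Purkinje-cell response barcodes
# ---------------------------------------------------------------------------

def motor_regressor(bout_flag: np.ndarray, fs: float) -> np.ndarray:
    """Bout flag convolved with the causal GCaMP6s kernel."""
    b = np.asarray(bout_flag, dtype=float)
    if not np.isin(b, (0.0, 1.0)).all():
        raise ValueError("bout_flag must be binary")
    return np.convolve(b, gcamp_kernel(fs))[: b.size]


def first_bout_responses(trace: np.ndarray, first_bout_onsets: np.ndarray,
                         fs: float, pre_s: float = 1.0,
                         response_s: float = 1.2) -> np.ndarray:
    """Per-trial first-bout-triggered responses of one trace.

    ``first_bout_onsets`` holds one sample index per trial (negative when
    the trial has no first bout).  Each response is the mean fluorescence
    0..1.2 s after the onset minus the mean of the preceding second (the
    2.2 s triggered window used for Purkinje-cell recordings).
    """
    trace = np.asarray(trace, dtype=float)
    n_pre = int(round(pre_s * fs))
    n_resp = int(round(response_s * fs))
    out = np.full(len(first_bout_onsets), np.nan)
    for i, t0 in enumerate(np.asarray(first_bout_onsets, dtype=int)):
        if t0 < n_pre or t0 + n_resp > trace.size:
            continue
        baseline = trace[t0 - n_pre : t0].mean()
        out[i] = trace[t0 : t0 + n_resp].mean() - baseline
    return out


_BLOCKS = ("pre", "ad_first", "ad_last", "post_first", "post_last")


def _block_indices(phases: np.ndarray) -> dict[str, np.ndarray]:
    phases = np.asarray(phases)
    pre = np.flatnonzero(phases == "pre_adaptation")
    ad = np.flatnonzero(phases == "adaptation")
    post = np.flatnonzero(phases == "post_adaptation")
    if ad.size < 20 or post.size < 20 or pre.size < 10:
        raise ValueError("too few trials for the four transition criteria")
    return {
        "pre": pre[-10:],
        "ad_first": ad[:10],
        "ad_last": ad[-10:],
        "post_first": post[:10],
        "post_last": post[-10:],
    }


def compute_criteria(responses_per_trial, phases) -> np.ndarray:
    """Four protocol-transition criteria from per-trial bout responses.

    Block means of the first-bout-triggered response (0-1.2 s window means,
    computed upstream) over ten-trial blocks; trials without a first bout
    (NaN) are skipped.  Criterion 1: adaptation start vs pre-adaptation;
    2: adaptation end vs start; 3: post start vs adaptation end; 4: post end
    vs post start.
    """
    r = np.asarray(responses_per_trial, dtype=float)
    blocks = _block_indices(phases)
    m = {k: np.nanmean(r[v]) if np.any(~np.isnan(r[v])) else np.nan
         for k, v in blocks.items()}
    return np.array([
        m["ad_first"] - m["pre"],
        m["ad_last"] - m["ad_first"],
        m["post_first"] - m["ad_last"],
        m["post_last"] - m["post_first"],
    ])


def barcode(
    responses_per_trial,
    phases,
    n_shuffles: int = 100_000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> str:
    """Ternary 4-character response barcode via a trial-shuffling null.

    Non-calibration trials are randomly permuted ``n_shuffles`` times; all
    four criteria are recomputed per permutation, yielding a shared null.
    A criterion above its 97.5th null percentile becomes '+', below the
    2.5th '-', otherwise '0'.  The decline-and-recovery profile of an
    internal-model unit reads "0-0+".
    """
    r = np.asarray(responses_per_trial, dtype=float)
    phases = np.asarray(phases)
    obs = compute_criteria(r, phases)
    noncal = np.flatnonzero(phases != "calibration")
    if noncal.size < 20:
        raise ValueError("need at least 20 non-calibration trials")
    blocks = _block_indices(phases)
    # positions of each block within the non-calibration index list
    pos = {k: np.searchsorted(noncal, v) for k, v in blocks.items()}

    rng = np.random.default_rng(seed)
    vals = r[noncal]
    perm_mat = rng.permuted(np.tile(vals, (n_shuffles, 1)), axis=1)
    with np.errstate(all="ignore"):
        m = {k: np.nanmean(perm_mat[:, p], axis=1) for k, p in pos.items()}
    null = np.stack([
        m["ad_first"] - m["pre"],
        m["ad_last"] - m["ad_first"],
        m["post_first"] - m["ad_last"],
        m["post_last"] - m["post_first"],
    ])
    lo = np.nanpercentile(null, percentiles[0], axis=1)
    hi = np.nanpercentile(null, percentiles[1], axis=1)
    symbols = []
    for k in range(4):
        if np.isnan(obs[k]):
            symbols.append("0")
        elif obs[k] > hi[k]:
            symbols.append("+")
        elif obs[k] < lo[k]:
            symbols.append("-")
        else:
            symbols.append("0")
    return "".join(symbols)


def cluster_enrichment(
    barcodes_per_fish: list[list[str]],
    groups: list[str],
    alpha: float = 0.05,
    display_floor: float = 0.02,
) -> pd.DataFrame:
    """Per-cluster ROI fractions and Kruskal-Wallis enrichment across groups.

    ``barcodes_per_fish[i]`` holds the barcodes of all ROIs of fish i and
    ``groups[i]`` its experimental group.  Within-fish fractions are
    compared across groups per cluster; clusters whose mean fraction
    reaches 2% in at least one group are marked ``displayed`` (the
    reporting filter).
    """
    if len(barcodes_per_fish) != len(groups):
        raise ValueError("one group label per fish required")
    group_names = sorted(set(groups))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    clusters = sorted({b for fish in barcodes_per_fish for b in fish})
    frac = pd.DataFrame(0.0, index=range(len(groups)), columns=clusters)
    for i, fish in enumerate(barcodes_per_fish):
        if len(fish) == 0:
            raise ValueError(f"fish {i} has no ROIs")
        s = pd.Series(fish).value_counts(normalize=True)
        frac.loc[i, s.index] = s.values
    rows = []
    for c in clusters:
        samples = [frac.loc[[i for i, g in enumerate(groups) if g == gn], c].to_numpy()
                   for gn in group_names]
        if any(s.size == 0 for s in samples):
            raise ValueError("every group needs at least one fish")
        if np.unique(np.concatenate(samples)).size == 1:
            p = 1.0
        else:
            p = float(stats.kruskal(*samples).pvalue)
        means = {f"mean_frac_{gn}": float(s.mean()) for gn, s in zip(group_names, samples)}
        rows.append({"cluster": c, "pvalue": p, "significant": p < alpha,
                     "displayed": max(means.values()) >= display_floor, **means})
    return pd.DataFrame(rows)


@dataclass
class RoiTraceSet:
    """Fluorescence traces of a set of ROIs with trigger annotations."""

    traces: np.ndarray                     # (n_rois, n_samples), z-scored a.u.
    fs: float                              # Hz
    grating_onsets: np.ndarray = field(default_factory=lambda: np.array([], int))
    bout_onsets: np.ndarray = field(default_factory=lambda: np.array([], int))
    first_bout_onsets: np.ndarray = field(default_factory=lambda: np.array([], int))
    trial_phase: np.ndarray = field(default_factory=lambda: np.array([], object))
    ground_truth: pd.DataFrame | None = None

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]
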