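"""Calcium-imaging analyses on synthetic fluorescence and a synthetic volume.

Generates ROI traces for a controller-driven imaging session (sensor,
integrator, motor, internal-model-like and noise units), then runs the
analysis chain: time-constant fitting for the sensory units, ternary
response barcoding for the trial-modulated unit, and correlation-map
segmentation of a small volumetric movie with planted somata.
"""

import numpy as np

from boutloop import controller as ct
from boutloop import imaging as im
from boutloop import reafference as rf
from boutloop import synth as sy

# --- time constants -------------------------------------------------------
proto = rf.build_protocol("whole_brain_imaging")
rec, _ = sy.gen_tail_session(proto, seed=3, behaver=ct.REFERENCE_PARAMS)
fs = 1.5
t = np.arange(0, proto.total_duration_s, 1 / fs)
shown = np.interp(t, rec.time, rec.grating_shown)

specs = [sy.RoiSpec("sensor", tau_s=0.5, snr=5),
         sy.RoiSpec("integrator", tau_s=4.0, snr=5)]
rts = sy.gen_fluorescence(proto, rec, specs, fs=fs, seed=0)
for i, spec in enumerate(specs):
    tr = im.preprocess_trace(rts.traces[i], fs, "whole_brain")
    tau, r, label = im.fit_time_constant(tr, shown, fs,
                                         preprocess_mode="whole_brain")
    print(f"true tau {spec.tau_s:.1f} s -> fitted {tau:.1f} s "
          f"(corr {r:.2f}, {label})")

# --- response barcodes ----------------------------------------------------
proto_pc = rf.build_protocol("pc_imaging", "lag_trained")
rec_pc, _ = sy.gen_tail_session(proto_pc, seed=4, behaver=ct.REFERENCE_PARAMS)
rts_pc = sy.gen_fluorescence(proto_pc, rec_pc,
                             [sy.RoiSpec("barcode", profile="0-0+", snr=3)],
                             fs=5.0, seed=1)
tr = im.preprocess_trace(rts_pc.traces[0], 5.0, "pc")
resp = im.first_bout_responses(tr, rts_pc.first_bout_onsets, 5.0)
bc = im.barcode(resp, rts_pc.trial_phase, n_shuffles=10_000, seed=2)
print(f"\nplanted decline-and-recovery unit -> barcode {bc!r}")
print("('0-0+': response falls during lag training and recovers afterwards,"
      "\n the profile expected of an internal-model unit)")

# --- ROI segmentation -----------------------------------------------------
movie, masks, _ = sy.gen_volume(6, seed=2)
labels, traces = im.segment_rois(movie)
print(f"\nplanted somata: {len(masks)}, segmented ROIs: {labels.max()}")
areas = [(labels == l).sum() * 0.36 for l in range(1, labels.max() + 1)]
print("ROI areas (um^2):", np.round(areas, 1))
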