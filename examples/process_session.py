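"""Simulate one reactive-hyperaemia session and measure its index.

Synthesizes a 15.5-minute dual-arm recording (baseline / cuff occlusion /
release) with a known dilation response of 0.5, runs the full measurement
chain, and prints what it computed.  The raw index should land near the
planted dilation; quality-control flags would name anything the pipeline
distrusted.
"""

from ramdi import (
    HyperaemiaResponse,
    SubjectProfile,
    compute_ra_mdi,
    synth_session,
)

subject = SubjectProfile("demo01", age=40, sex="male", sbp=120, dbp=75, bmi=24)
response = HyperaemiaResponse(dilation_amplitude=0.5)  # 50% envelope increase at peak
rec, truth = synth_session(subject, resp=response, seed=42)

print(f"recording: {rec.n_samples} samples/arm at {rec.fs:g} Hz "
      f"({rec.duration_s / 60:.1f} min), {len(truth.beat_peak_times_s)} true beats")

result = compute_ra_mdi(rec)
print(f"occlusion complete: {result.occlusion.complete} "
      f"(pulse-band residual {result.occlusion.residual_ratio:.3f}, truth {truth.occlusion_residual})")
print(f"raw index:        {result.raw_index:.3f}   (planted dilation {response.dilation_amplitude})")
print(f"ra_mdi:           {result.ra_mdi:.3f}   (adjustment factor {result.adjustment_factor:g})")
print(f"qc flags:         {result.qc_flags or '(none)'}")
for phase, s in result.phase_summaries["occluded"].items():
    print(f"  occluded {phase:10s} hr {s.mean_hr:6.1f} bpm   envelope {s.median_envelope:6.3f}   "
          f"valid {s.valid_fraction:.0%}")
# The raw index reads slightly below the planted peak dilation because the
# 30 s envelope windows average over the rise and fall of the response.
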