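"""Simulate one normal and one shuffling circular walk, then compute the
seven gait indices and their screening flags.

The shuffling preset drags the feet (step height ÷ 10), so its leg-normalized
heel vertical amplitude collapses below the 0.1 screening cutoff while every
other index stays close to the normal walk.
"""

from gaitplane import compute_indices, preset, project_recording, simulate_recording

for name in ("normal", "shuffling"):
    params = preset(name, seed=42)
    recording = simulate_recording(params, subject_id=f"demo-{name}")
    tracks = project_recording(recording, score_threshold=0.7)
    report = compute_indices(tracks, level=0.75)
    idx = report.indices

    print(f"\n{name} gait — {recording.n_frames} frames, "
          f"leg length {tracks.lengths.leg:.3f} m")
    print(f"  hip angle range        {idx.hip_angle_range.value:6.1f} deg "
          f"(flag below 30)")
    print(f"  knee angle range       {idx.knee_angle_range.value:6.1f} deg "
          f"(flag below 45)")
    print(f"  heel vertical amplitude{idx.heel_vertical_amplitude.value:7.3f}     "
          f"(flag below 0.1, leg = 1)")
    print(f"  foot angle             {idx.foot_angle.value:6.1f} deg (no cutoff)")
    print(f"  heel outward shift     {idx.heel_outward_shift.value:+7.3f}    "
          f"(flag above -0.08)")
    print(f"  toe outward shift      {idx.toe_outward_shift.value:+7.3f}    "
          f"(flag above 0.18)")
    print(f"  leg outward shift      {idx.leg_outward_shift.value:+7.3f}    "
          f"(flag above 0.1)")
    raised = [k for k, v in report.flags.items() if v]
    print(f"  flags raised: {raised or 'none'}")
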