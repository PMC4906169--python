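"""Link foci detections into trajectories and estimate migration speeds.

Generates 500 constant-velocity tracks at the wild-type speed distribution
(255 +- 128 nm/min) with 50 nm localization noise, links them, and compares
the slope-method speed (unbiased) with the stepwise method (noise-inflated).
"""

from golgiring import generate_track_set, link_trajectories, preset, speeds_table

spec = preset("wt_speed")
detections, truth = generate_track_set(spec, seed=1)
tracks = link_trajectories(detections[["frame", "x_nm", "y_nm", "intensity"]])

slope = speeds_table(tracks, spec.frame_interval, method="slope")
step = speeds_table(tracks, spec.frame_interval, method="stepwise")

print(f"tracks generated/recovered: {spec.n_tracks}/{len(tracks)}")
print(f"generative mean speed:      {truth.table.true_speed_nm_min.mean():.1f} nm/min")
print(f"slope-method mean:          {slope.speed_nm_min.mean():.1f} nm/min")
print(f"stepwise-method mean:       {step.speed_nm_min.mean():.1f} nm/min")

# The slope method projects each track onto its principal axis and fits
# position vs time, cancelling isotropic localization noise; the stepwise
# mean displacement adds ~sqrt(v^2 dt^2 + 4 sigma_loc^2) per step and
# overestimates badly at 50 nm noise - which is why slope is the default.
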