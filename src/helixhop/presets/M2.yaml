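# Dimeric MKLP1 (M2) cohort preset.
# The preference vector is solved at load time so the noise-free expected
# velocities match the construct's measured cohort means:
#   longitudinal  k * (p1+p2+p3-p6-p7-p8) * 8 nm  = v_long
#   rotational    k * (p1-p3+p4-p5+p6-p8) / n     = v_rot
# corner_preference fixes p1=p3=p6=p8; lateral_preference_total fixes p4+p5.
construct: M2
n_tracks: 36
window_s: 0.3
duration_s: 30.0
k_total: 45.0
v_long_um_s: 0.30
v_rot_rev_s: 0.37
corner_preference: 0.01
lateral_preference_total: 0.115
trap_on_rate: 0.08695652173913043   # ~8% trapped occupancy
trap_off_rate: 1.0                  # mean trapped dwell 1 s
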