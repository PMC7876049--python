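# Monomeric MKLP1 (M1) cohort preset; see M2.yaml for the meaning of keys.
construct: M1
n_tracks: 47
window_s: 0.4
duration_s: 30.0
k_total: 40.0
v_long_um_s: 0.24
v_rot_rev_s: 0.11
corner_preference: 0.02
lateral_preference_total: 0.08
trap_on_rate: 0.08695652173913043
trap_off_rate: 1.0
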