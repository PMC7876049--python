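# Centralspindlin heterotetramer (M2C2) cohort preset; see M2.yaml for the
# meaning of the keys.  Larger background preferences reflect the weaker
# directional bias (occasional backward and rightward hops).
construct: M2C2
n_tracks: 47
window_s: 0.5
duration_s: 30.0
k_total: 45.0
v_long_um_s: 0.19
v_rot_rev_s: 0.12
corner_preference: 0.03
lateral_preference_total: 0.10
trap_on_rate: 0.08695652173913043
trap_off_rate: 1.0
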