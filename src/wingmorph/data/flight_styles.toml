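# Metric combination assigned to each flight style. Directions apply to the
# raw metric value; "low_optimal" on TA means acute (pointed) tips score
# highest, "high_optimal" on TA is the inverted broad-tip-optimal reading
# used for lift-demanding styles.

[marine_soaring]
metrics = [["2MA", "high_optimal"], ["TA", "low_optimal"]]

[aerial_predation]
metrics = [["2MA", "high_optimal"], ["PA", "high_optimal"], ["TA", "high_optimal"]]

[thermal_soaring]
metrics = [["TA", "low_optimal"]]

[diving]
metrics = [["2MA", "high_optimal"], ["PA", "high_optimal"]]

[hovering]
metrics = [["2MA", "high_optimal"], ["PA", "high_optimal"]]

[long_distance_migration]
metrics = [["AR", "high_optimal"], ["TA", "low_optimal"]]

[burst_flapping]
metrics = [["TA", "high_optimal"]]
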