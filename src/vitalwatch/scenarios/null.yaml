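# Null-calibration scenario: group labels are a pure random labelling.
# Monitoring is a fixed 24 h and the during-group's first SAE is pinned to
# monitoring end, so every patient's exposure window is the same 24 h and
# no physiologic effect distinguishes the groups.
n_patients: 200
monitoring_hours: 24
sae_time_mode: end_of_monitoring
spo2_interval_s: 60
gap_rate_per_hour: {HR: 0.0, RR: 0.0, SPO2: 0.0}
artifact_rate: {HR: 0.0, RR: 0.0, SPO2: 0.0, SBP: 0.0}
sbp_dropout: 0.0
pre_sae_effect: {}
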