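# Effect-recovery scenario: a step rise in heart rate over the 6 h before
# the first SAE makes sustained HR > 110 common only ahead of an SAE that
# occurs during monitoring. Windows are otherwise identical 24-h exposures.
n_patients: 491
monitoring_hours: 24
sae_time_mode: end_of_monitoring
spo2_interval_s: 60
gap_rate_per_hour: {HR: 0.0, RR: 0.0, SPO2: 0.0}
artifact_rate: {HR: 0.0, RR: 0.0, SPO2: 0.0, SBP: 0.0}
sbp_dropout: 0.0
pre_sae_effect: {HR: 45.0}
pre_sae_effect_hours: 6
pre_sae_effect_shape: step
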