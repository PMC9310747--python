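# Full-realism cohort: 491 patients monitored 79 h (capped at 96 h),
# sub-minute pulse oximetry, clock-anchored intermittent blood pressure,
# device-removal gaps, artefact contamination, and a modest ramped
# pre-SAE shift (tachycardia + hypotension) over the 12 h before the SAE.
n_patients: 491
monitoring_hours: 79
spo2_interval_s: 10
pre_sae_effect: {HR: 14.0, SBP: -14.0}
pre_sae_effect_hours: 12
pre_sae_effect_shape: ramp
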