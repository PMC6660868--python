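establishment_id,risk_id,severity,occurrence,affectation
dairy-001,R1_microbiological_quality_failure,5,3,5
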