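cosewic_status,risk_weight
Not Assessed,0
Non-active,0
Data Deficient,0
Not at Risk,0
Special Concern,0.2
Threatened,0.4
Endangered,0.6
Extinct,1
Extirpated,1
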