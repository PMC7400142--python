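# PROVISIONAL fixture: consensus relations reported to fall below the 5.0
# display cutoff of the final model (named in the study's limitations).
# Weights are SYNTHETIC sub-threshold stand-ins (4.5); display=false marks
# them as retained-but-hidden.  Excluded from the published-table tests.
source,target,weight,sign,display,category,attestation
german_language,health_care,4.5,+,false,below,edge
residence_security,social_care,4.5,+,false,below,edge
housing,daily_activities,4.5,+,false,below,edge
access_to_education,sociocultural_adaptation,4.5,+,false,below,edge
sociocultural_adaptation,access_to_education,4.5,+,false,below,edge
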