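# Published group-average impact of each main risk factor on the outcome
# (0-1 scale: mean 0-10 impact rating divided by 10).
factor,impact
social_contacts,0.78
housing,0.77
health_care,0.77
social_care,0.75
daily_activities,0.72
residence_security,0.70
access_to_education,0.67
income_security,0.65
sociocultural_adaptation,0.58
political_climate,0.53
german_language,0.52
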