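# Text-attested edge list of the final consensus system model (24 of the
# ~29 drawn edges; the remainder are visible only in the published figure
# and are deliberately omitted as non-citable).  The study publishes no
# numeric edge weights, only colour categories for some edges; the weight
# column therefore carries SYNTHETIC category-representative values
# (medium->5.5, strong->6.5, powerful->7.5, category unstated->6.0).
# Do not treat weights as measured data; counts, directions, and stated
# categories are the attested content.  attestation: category = the text
# names the influence category; edge = only the edge's existence is stated.
source,target,weight,sign,display,category,attestation
political_climate,social_contacts,6.5,+,true,strong,category
german_language,social_contacts,6.5,+,true,strong,category
sociocultural_adaptation,social_contacts,6.0,+,true,,edge
daily_activities,social_contacts,5.5,+,true,medium,category
social_care,social_contacts,6.0,+,true,,edge
access_to_education,social_contacts,6.0,+,true,,edge
social_contacts,german_language,6.5,+,true,strong,category
social_contacts,sociocultural_adaptation,6.0,+,true,,edge
social_contacts,daily_activities,6.0,+,true,,edge
german_language,sociocultural_adaptation,6.5,+,true,strong,category
sociocultural_adaptation,german_language,7.5,+,true,powerful,category
german_language,access_to_education,6.5,+,true,strong,category
access_to_education,german_language,6.5,+,true,strong,category
german_language,income_security,6.0,+,true,,edge
access_to_education,daily_activities,6.0,+,true,,edge
access_to_education,income_security,6.0,+,true,,edge
income_security,housing,6.0,+,true,,edge
income_security,daily_activities,6.0,+,true,,edge
income_security,health_care,6.0,+,true,,edge
residence_security,housing,5.5,+,true,medium,category
residence_security,access_to_education,5.5,+,true,medium,category
residence_security,income_security,6.5,+,true,strong,category
political_climate,social_care,6.0,+,true,,edge
political_climate,residence_security,6.0,+,true,,edge
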