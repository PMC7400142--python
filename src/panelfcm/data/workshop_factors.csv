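# Raw risk factors elicited in the two system-model workshops
# (scientists' panel and practitioners' panel), one row per card cluster.
label,source_panel
Contacts in host country,scientists
Persons of trust,scientists
Friends,scientists
Housing,scientists
Professional care services (social and health),scientists
Occupational opportunities,scientists
Leisure activities,scientists
Residence status,scientists
Education,scientists
Income security,scientists
Adaptation,scientists
Social climate,scientists
Language,scientists
Future perspectives,scientists
Family reunification,scientists
Experiences of exclusion,scientists
Informal relationships,practitioners
Housing,practitioners
Culture-sensitive medical care,practitioners
Professional and adequate relationship opportunities,practitioners
Daily structure,practitioners
Residence status,practitioners
Language and education,practitioners
Contact with family and family remittances,practitioners
Personal resources,practitioners
Social climate,practitioners
Future perspectives,practitioners
Warranty of rights,practitioners
Criminal conduct,practitioners
Prior information about dangers of flight and circumstances in the EU,practitioners
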