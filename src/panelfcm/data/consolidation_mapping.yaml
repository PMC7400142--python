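# Consolidation of the raw workshop factors into the 11 main risk factors
# of the final system model (keep / merge / split / exclude decisions of the
# third workshop).  Raw labels are matched case-insensitively after
# whitespace normalization.
main_factors:
  - id: social_contacts
    name: Social contacts
    description: Social contacts and relationships in the host country
  - id: housing
    name: Housing
    description: Housing situation (living arrangements and conditions)
  - id: health_care
    name: Health care
    description: Professional health care services
  - id: social_care
    name: Social care
    description: Professional social care services
  - id: daily_activities
    name: Daily activities
    description: Daily structure and leisure activities
  - id: residence_security
    name: Residence security
    description: Right to reside in the host country (legal certainty)
  - id: access_to_education
    name: Access to education
    description: Access to education and training in the host country
  - id: income_security
    name: Income security
    description: Ability to meet basic needs without fear of losing income
  - id: sociocultural_adaptation
    name: Sociocultural adaptation
    description: Competence to fit into the cultural environment of the host country
  - id: political_climate
    name: Political and social climate
    description: Attitude of politics and society towards refugees in the host country
  - id: german_language
    name: German language skills
    description: Ability to use the host-country language
actions:
  - action: merge
    raw:
      - {label: Contacts in host country, panel: scientists}
      - {label: Persons of trust, panel: scientists}
      - {label: Friends, panel: scientists}
      - {label: Informal relationships, panel: practitioners}
    targets: [social_contacts]
  - action: merge
    raw:
      - {label: Housing, panel: scientists}
      - {label: Housing, panel: practitioners}
    targets: [housing]
  - action: split
    raw:
      - {label: Professional care services (social and health), panel: scientists}
    targets: [health_care, social_care]
    rationale: single raw factor split into two main risk factors
  - action: keep
    raw:
      - {label: Culture-sensitive medical care, panel: practitioners}
    targets: [health_care]
  - action: keep
    raw:
      - {label: Professional and adequate relationship opportunities, panel: practitioners}
    targets: [social_care]
  - action: merge
    raw:
      - {label: Occupational opportunities, panel: scientists}
      - {label: Leisure activities, panel: scientists}
      - {label: Daily structure, panel: practitioners}
    targets: [daily_activities]
  - action: merge
    raw:
      - {label: Residence status, panel: scientists}
      - {label: Residence status, panel: practitioners}
    targets: [residence_security]
  - action: keep
    raw:
      - {label: Education, panel: scientists}
    targets: [access_to_education]
  - action: split
    raw:
      - {label: Language and education, panel: practitioners}
    targets: [german_language, access_to_education]
    rationale: single raw factor split into two main risk factors
  - action: merge
    raw:
      - {label: Income security, panel: scientists}
      - {label: Contact with family and family remittances, panel: practitioners}
    targets: [income_security]
    # The published table files family contact/remittances under income
    # security, while the accompanying text says it was initially subsumed
    # there and excluded afterward; this mapping follows the table.
    rationale: family remittances subsumed under income security per the published table
  - action: merge
    raw:
      - {label: Adaptation, panel: scientists}
      - {label: Personal resources, panel: practitioners}
    targets: [sociocultural_adaptation]
  - action: merge
    raw:
      - {label: Social climate, panel: scientists}
      - {label: Social climate, panel: practitioners}
    targets: [political_climate]
  - action: keep
    raw:
      - {label: Language, panel: scientists}
    targets: [german_language]
  - action: exclude
    raw:
      - {label: Future perspectives, panel: scientists}
      - {label: Future perspectives, panel: practitioners}
    rationale: already covered by income security and residence security
  - action: exclude
    raw:
      - {label: Family reunification, panel: scientists}
    rationale: ambiguous direction of effect; not clearly post-migration
  - action: exclude
    raw:
      - {label: Experiences of exclusion, panel: scientists}
    rationale: treated as an output of the political and social climate
  - action: exclude
    raw:
      - {label: Warranty of rights, panel: practitioners}
    rationale: rarely named
  - action: exclude
    raw:
      - {label: Criminal conduct, panel: practitioners}
    rationale: mix of post- and pre-migration factors
  - action: exclude
    raw:
      - {label: Prior information about dangers of flight and circumstances in the EU, panel: practitioners}
    rationale: mix of post- and pre-migration factors
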