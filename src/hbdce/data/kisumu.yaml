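# Differentiated HIV service-delivery choice experiment, Kisumu (Kenya):
# 7 attributes, 23 levels, 10 partial-profile tasks of 3 alternatives
# showing 4 attributes each, 12 questionnaire versions, forced choice.
name: kisumu-dsd
design:
  tasks_per_respondent: 10
  alternatives_per_task: 3
  attributes_shown_per_task: 4
  questionnaire_versions: 12
  forced_choice: true
attributes:
  - name: Location of ART refills
    levels: [Health facility, Community meeting point, Home]
  - name: Frequency of ART refills
    levels: [Every month, Every 3 months, Every 6 months]
  - name: Person providing ART refills
    levels: [Nurse, Lay health worker, Pharmacist, PLHIV peer]
  - name: Adherence support
    levels: [No support, Individual support, Group support]
  - name: Refill pickup time
    levels: [Weekday regular hours, Weekday off hours, Weekend]
  - name: Location of clinical review
    levels: [Health facility, Community meeting point, Home]
  - name: Frequency of clinical visits
    levels: [Every month, Every 3 months, Every 6 months, Every 12 months]
prohibitions:
  # a facility ART refill combined with a home clinical/viral-load visit is
  # not operationally plausible and was excluded from the questionnaires
  - attribute_a: Location of ART refills
    level_a: Health facility
    attribute_b: Location of clinical review
    level_b: Home
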