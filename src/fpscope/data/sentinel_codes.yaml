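# Sentinel OHIP fee-code taxonomy: 18 broad services that Ontario family
# physicians may provide.  Each service is defined by fee codes unique to it
# (explicit codes and/or numeric ranges and/or a code-suffix rule) plus an
# annual threshold: the minimum number of qualifying billed events per year
# for a physician to count as providing the service.
#
# Ranges use the notation "Z491-Z499" (same alphabetic prefix, inclusive
# numeric span).  Suffix rules capture any code whose final character matches,
# after explicit codes and ranges of every service have been checked.
services:
  - service_id: clinic
    display_name: Clinic
    abbrev: CL
    codes: [A001, A003, A004, A007, A008, A005, A006, Q200, A911, A912,
            G700, G845, G847, G373, G590]
    threshold: 50
    threshold_unit_label: visits
  - service_id: anaesthesia
    display_name: Anaesthesia
    abbrev: AN
    codes: [S205C, S206C, S207C, S287C, S323C, S332C, S329C, S339C, S340C,
            S321C, S165C, S166C, S167C, S171C, S175C, S176C, S177C, S188C,
            E022C, E023C, P018C, P014C, P016C]
    threshold: 10
    threshold_unit_label: procedures
  - service_id: emergency_medicine
    display_name: Emergency Medicine
    abbrev: EM
    codes: [H101, H102, H103, H151, H152, H153, H121, H122, H123, H131,
            H132, H133, A888, A100]
    threshold: 50
    threshold_unit_label: visits
  - service_id: hospital_medicine
    display_name: Hospital Medicine
    abbrev: HM
    codes: [C002, C003, C004, C007, C009, C008, C122, C123, C124, C911,
            C912, C933, A933]
    threshold: 25
    threshold_unit_label: visits
  - service_id: home_visits
    display_name: Home Visits
    abbrev: HV
    codes: [A900, A901, A902]
    threshold: 10
    threshold_unit_label: visits
  - service_id: mental_health
    display_name: Mental Health
    abbrev: MH
    codes: [K004, K007, K010, K012, K013, K019, K020, K024, K025, K040,
            K041, K005, K006]
    threshold: 25
    threshold_unit_label: visits
  # W008 appears twice in the published fee-code list; duplicates within one
  # service are collapsed on load.
  - service_id: long_term_care
    display_name: Long-term Care
    abbrev: LT
    codes: [W001, W002, W003, W004, W008, W010, W105, W008]
    threshold: 25
    threshold_unit_label: visits
  - service_id: obstetrics
    display_name: Obstetric Deliveries
    abbrev: OB
    codes: [P006, P009]   # vaginal delivery
    threshold: 2
    threshold_unit_label: deliveries
  - service_id: palliative_care
    display_name: Palliative Care
    abbrev: PC
    codes: [C882, A945, K023, B997, B998, B966, G512, C945, E083, E084]
    threshold: 10
    threshold_unit_label: visits
  - service_id: surgical_assisting
    display_name: Surgical Assisting
    abbrev: SA
    codes: []
    suffixes: [B]          # any fee code ending in B, unless claimed above
    threshold: 10
    threshold_unit_label: procedures
  - service_id: chemotherapy
    display_name: Chemotherapy Administration
    abbrev: CA
    codes: [G381, G345, G359]
    threshold: 10
    threshold_unit_label: visits
  - service_id: sports_medicine
    display_name: Sports Medicine
    abbrev: SM
    codes: [A917]
    threshold: 25
    threshold_unit_label: visits
  - service_id: chronic_pain
    display_name: Chronic Pain
    abbrev: CP
    codes: [A937, K707, K037]
    threshold: 25
    threshold_unit_label: visits
  - service_id: care_of_the_elderly
    display_name: Care of the Elderly
    abbrev: CE
    codes: [A967]
    threshold: 25
    threshold_unit_label: visits
  - service_id: addiction_medicine
    display_name: Addiction Medicine
    abbrev: AM
    codes: [K682, K683, K684, A957, A680, C680, K680]
    threshold: 25
    threshold_unit_label: visits
  # G379 appears twice in the published fee-code list; collapsed on load.
  - service_id: endoscopy
    display_name: Endoscopy
    abbrev: EN
    codes: [G379, Z399, Z400, E702, E797, E798, G379, Z491-Z499, Z555,
            E740, E741, E747, E705, Z571, E720, Z580]
    threshold: 10
    threshold_unit_label: visits
  - service_id: allergy
    display_name: Allergy Medicine
    abbrev: AL
    codes: [A927]
    threshold: 25
    threshold_unit_label: visits
  - service_id: sleep_medicine
    display_name: Sleep Medicine
    abbrev: SL
    codes: [A947]
    threshold: 25
    threshold_unit_label: visits
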