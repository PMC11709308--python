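# Reference regional summary of the 2017 Ontario family-physician cohort:
# physician counts, demographics, per-service provider counts and the
# number-of-services distribution by the four region strata, as published.
# Suppressed cells (counts of 1-6, withheld for privacy) are transcribed as
# the marker "<=6"; their true counts were never released, so `raw` is
# unknown for them and the affected row totals are ranges.
#
# The published province-wide cohort was 14,443 family physicians; the four
# region strata of this table sum to 12,984.  The gap is unexplained in the
# source (plausibly physicians unassignable to a region stratum); both
# numbers are recorded and no reconciliation is attempted.
meta:
  study_year: 2017
  province_cohort_size: 14443
  suppression_cutoff: 6
columns: [north_rural, north_urban, south_rural, south_urban]
rows:
  - {row_id: total_physicians, label: Total Physicians, kind: physicians,
     cells: [293, 545, 759, 11387], total: 12984}
  - {row_id: female, label: Total Females, kind: female,
     cells: [118, 235, 328, 5300], percents: [40, 43, 43, 47],
     total: 5981, total_percent: 46}
  - {row_id: stage_lt10, label: "<10", kind: stage,
     cells: [144, 233, 333, 4243], percents: [49, 43, 44, 37],
     total: 4953, total_percent: 38}
  - {row_id: stage_10_19, label: "10-19", kind: stage,
     cells: [55, 91, 126, 2172], percents: [19, 17, 17, 19],
     total: 2444, total_percent: 19}
  - {row_id: stage_20_29, label: "20-29", kind: stage,
     cells: [70, 132, 190, 3337], percents: [24, 24, 25, 29],
     total: 3729, total_percent: 29}
  - {row_id: stage_gt29, label: ">29", kind: stage,
     cells: [24, 89, 110, 1635], percents: [8, 16, 14, 14],
     total: 1858, total_percent: 14}
  - {row_id: svc_clinic, label: Clinic, kind: service,
     cells: [259, 439, 666, 9838], percents: [88, 81, 88, 86],
     total: 11202, total_percent: 86}
  - {row_id: svc_mental_health, label: Mental Health, kind: service,
     cells: [113, 299, 511, 7737], percents: [39, 55, 67, 68],
     total: 8660, total_percent: 67}
  - {row_id: svc_emergency_medicine, label: Emergency Medicine, kind: service,
     cells: [197, 305, 483, 6511], percents: [67, 56, 64, 57],
     total: 7496, total_percent: 58}
  - {row_id: svc_palliative_care, label: Palliative Care, kind: service,
     cells: [196, 282, 502, 2897], percents: [67, 52, 66, 25],
     total: 3877, total_percent: 30}
  - {row_id: svc_hospital_medicine, label: Hospital Medicine, kind: service,
     cells: [224, 280, 452, 1936], percents: [76, 51, 60, 17],
     total: 2892, total_percent: 22}
  - {row_id: svc_home_visits, label: Home Visits, kind: service,
     cells: [27, 72, 206, 1835], percents: [9, 13, 27, 16],
     total: 2140, total_percent: 16}
  - {row_id: svc_long_term_care, label: Long-term Care, kind: service,
     cells: [122, 65, 285, 1258], percents: [42, 12, 38, 11],
     total: 1730, total_percent: 13}
  - {row_id: svc_chronic_pain, label: Chronic Pain, kind: service,
     cells: ["<=6", 31, 47, 883], percents: [0, 6, 6, 8],
     total: [962, 967], total_percent: 7}
  - {row_id: svc_surgical_assisting, label: Surgical Assisting, kind: service,
     cells: [26, 51, 106, 819], percents: [9, 9, 14, 7],
     total: 1002, total_percent: 8}
  - {row_id: svc_anaesthesia, label: Anaesthesia, kind: service,
     cells: [17, 38, 58, 532], percents: [6, 7, 8, 5],
     total: 645, total_percent: 5}
  - {row_id: svc_obstetrics, label: Obstetric Deliveries, kind: service,
     cells: [26, 16, 39, 244], percents: [9, 3, 5, 2],
     total: 325, total_percent: 3}
  - {row_id: svc_addiction_medicine, label: Addiction Medicine, kind: service,
     cells: [0, 16, "<=6", 222], percents: [null, 3, 0, 2],
     total: [239, 244], total_percent: 2}
  - {row_id: svc_endoscopy, label: Endoscopy, kind: service,
     cells: [26, "<=6", 24, 98], percents: [9, 0, 3, 1],
     total: [149, 154], total_percent: 1}
  - {row_id: svc_sports_medicine, label: Sports Medicine, kind: service,
     cells: [0, 0, 0, 74], percents: [null, null, null, 1],
     total: 74, total_percent: 1}
  # The published total for this row carries a stray "%" on the range
  # ("18-33%"); it is transcribed as the plain range [18, 33].
  - {row_id: svc_chemotherapy, label: Chemotherapy Administration, kind: service,
     cells: ["<=6", "<=6", "<=6", 15], percents: [0, 1, 1, 0],
     total: [18, 33], total_percent: 0}
  - {row_id: svc_care_of_the_elderly, label: Care of the Elderly, kind: service,
     cells: [0, 0, 0, 0], total: 0}
  - {row_id: svc_allergy, label: Allergy Medicine, kind: service,
     cells: [0, 0, 0, 0], total: 0}
  - {row_id: svc_sleep_medicine, label: Sleep Medicine, kind: service,
     cells: [0, 0, 0, 0], total: 0}
  - {row_id: nsvc_1, label: "1", kind: n_services,
     cells: [38, 95, 68, 1544], percents: [13, 17, 9, 14],
     total: 1745, total_percent: 13}
  - {row_id: nsvc_2, label: "2", kind: n_services,
     cells: [28, 94, 83, 2943], percents: [10, 17, 11, 26],
     total: 3148, total_percent: 24}
  - {row_id: nsvc_3, label: "3", kind: n_services,
     cells: [29, 88, 117, 3333], percents: [10, 16, 15, 29],
     total: 3567, total_percent: 27}
  - {row_id: nsvc_4, label: "4", kind: n_services,
     cells: [59, 98, 106, 1688], percents: [20, 18, 14, 15],
     total: 1951, total_percent: 15}
  - {row_id: nsvc_5, label: "5", kind: n_services,
     cells: [62, 97, 122, 1033], percents: [21, 18, 16, 9],
     total: 1314, total_percent: 10}
  - {row_id: nsvc_6, label: "6", kind: n_services,
     cells: [41, 45, 125, 505], percents: [14, 8, 16, 4],
     total: 716, total_percent: 6}
  - {row_id: nsvc_7, label: "7", kind: n_services,
     cells: [24, 20, 93, 227], percents: [8, 4, 12, 2],
     total: 364, total_percent: 3}
  - {row_id: nsvc_8plus, label: ">=8", kind: n_services,
     cells: [12, 8, 45, 114], percents: [4, 1, 6, 1],
     total: 179, total_percent: 1}
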