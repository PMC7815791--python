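"""Published per-1000 outcomes of the ERSPC-calibrated comparison.

These are the per-pathway base-metric values reported for the regular
(PSA -> TRUSGB) versus MRI (PSA -> mpMRI -> MRIGB) screening comparison of
men aged 55–64 screened every 3 years.  They are *inputs* to the
derived-metric arithmetic (differences, percent changes, harm–benefit and
per-death-averted ratios), not outputs of this package's simulator: the
absolute counts depend on natural-history parameters calibrated to ERSPC
and Dutch registry data that were never published.
"""

PUBLISHED_PER_1000: dict[str, dict[str, float]] = {
    "men_biopsied": {"regular": 396.0, "mri": 278.0},
    "insignificant_detected": {"regular": 80.8, "mri": 58.9},
    "significant_detected": {"regular": 36.0, "mri": 51.3},
    "overdiagnosed": {"regular": 15.6, "mri": 8.9},
    "deaths_averted": {"regular": 8.53, "mri": 8.77},
    "life_years_gained": {"regular": 81.6, "mri": 85.0},
    "qalys_gained": {"regular": 77.0, "mri": 80.2},
}

#: Reported share of recorded-significant screen detections present in the
#: regular pathway but missed in the MRI pathway, man-matched.
PUBLISHED_PCT_SIGNIFICANT_MISSED = 10.8
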