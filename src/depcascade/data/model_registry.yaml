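# Registry of the nine cross-validated base models: name, feature source and
# pipeline id as printed in the study's model table, plus the feature lists
# this package resolves them to from its own data dictionary.
#
# feature_count is the printed count and is kept as registry metadata; the
# resolved list can differ where the source cohort carried columns (e.g. 26
# HRV indices across postures) that the generator does not emulate.
#
# The exact "Clinical 15" item list lives in an unavailable supplement; the
# list below is SYNTHETIC-REFERENCE-DERIVED: one Boruta importance pass over
# the 26 WHO-5 + PHQ-9 + WHODAS items on the reference synthetic cohort
# (n=581, seed 0), top 15 by median importance, frozen here.

models:
  - name: "Somatic metrics"
    model_type: Base
    modalities: "Waist-to-hip ratio, blood pressure, temperature"
    feature_count: 9
    pipeline: P1
    features:
      [waist_to_hip_ratio, systolic_bp_mmhg, diastolic_bp_mmhg,
       body_temperature_c, resting_heart_rate_bpm, waist_circumference_cm,
       hip_circumference_cm, body_weight_kg, bmi]
  - name: "HRV"
    model_type: Base
    modalities: "Heart rate variability measures"
    feature_count: 26
    pipeline: P4
    features:
      [hrv_heart_rate_lying_bpm, hrv_sdnn_lying_ms, hrv_rmssd_lying_ms,
       hrv_lf_lying_ms2, hrv_hf_lying_ms2, hrv_baevskii_lying]
  - name: "Lab"
    model_type: Base
    modalities: "Blood test values"
    feature_count: 36
    pipeline: P4
    features:
      [glucose_mg_dl, crp_mg_dl, ast_u_l, alt_u_l, ggt_u_l,
       total_cholesterol_mg_dl, triglycerides_mg_dl, ldl_mg_dl, hdl_mg_dl,
       non_hdl_mg_dl, hba1c_pct, leukocytes_10e9_l, erythrocytes_10e12_l,
       hemoglobin_g_dl, hematocrit_pct, platelets_10e9_l, neutrophils_10e9_l,
       monocytes_10e9_l, eosinophils_10e9_l, basophils_10e9_l,
       normoblasts_10e9_l, lymphocytes_10e9_l, tsh_uu_ml, cortisol_ug_dl,
       igf1_ng_ml, a1at_g_l]
  - name: "Biographic"
    model_type: Base
    modalities: "Biographical data + LSNS-6"
    feature_count: 18
    pipeline: P2
    features:
      [age_years, n_siblings, adults_in_household, working_hours_per_week,
       sex_female, binge_drinking, partnership, separation_12m, sport_weekly,
       employment_12m, biological_children, migration_background,
       moved_childhood, parents_separated, education, financial_difficulties,
       smoking, lsns6_total]
  - name: "somatic"
    model_type: Base
    modalities: "PHQ15"
    feature_count: 15
    pipeline: P3
    features:
      [phq15_i1, phq15_i2, phq15_i3, phq15_i4, phq15_i5, phq15_i6, phq15_i7,
       phq15_i8, phq15_i9, phq15_i10, phq15_i11, phq15_i12, phq15_i13,
       phq15_i14, phq15_i15]
  - name: "Depression items"
    model_type: Base
    modalities: "WHO-5 + PHQ-9"
    feature_count: 11
    pipeline: P3
    features:
      [who5_i1, who5_i2, who5_i3, who5_i4, who5_i5,
       phq9_i1, phq9_i2, phq9_i3, phq9_i4, phq9_i5, phq9_i6, phq9_i7,
       phq9_i8, phq9_i9]
  - name: "All clinical"
    model_type: Base
    modalities: "WHO-5 + UCLA + PHQ-9 + WHODAS2.0 + PC-PTSD + PHQ-15"
    feature_count: 19
    pipeline: P3
    features:
      [who5_total, ucla3_total, phq9_total, whodas_total, pcptsd_total,
       phq15_total]
  - name: "All self-rated"
    model_type: Base
    modalities: "All clinical + biographic + LSNS"
    feature_count: 16
    pipeline: P3
    features:
      [who5_total, ucla3_total, phq9_total, whodas_total, pcptsd_total,
       phq15_total, age_years, n_siblings, adults_in_household,
       working_hours_per_week, sex_female, binge_drinking, partnership,
       separation_12m, sport_weekly, employment_12m, biological_children,
       migration_background, moved_childhood, parents_separated, education,
       financial_difficulties, smoking, lsns6_total]
  - name: "Clinical 15"
    model_type: Base
    modalities: "WHO-5 + PHQ-9 + WHODAS2.0"
    feature_count: 15
    pipeline: P1
    features:
      [whodas_i8, whodas_i4, whodas_i1, whodas_i6, whodas_i2, whodas_i11,
       who5_i1, who5_i4, who5_i5, whodas_i9, phq9_i1, who5_i3, whodas_i7,
       phq9_i7, whodas_i5]
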