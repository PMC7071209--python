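# Fixture feature roster for the patient table: numeric anthropometrics and
# biochemistry, binary history items, and ordinal lifestyle-questionnaire
# items (levels 0/1/2; suffix 1 = before pregnancy, 2 = during pregnancy).
variables:
  - {name: age, block: anthropometric, type: numeric}
  - {name: weight, block: anthropometric, type: numeric}
  - {name: bmi, block: anthropometric, type: numeric}
  - {name: gestational_age, block: anthropometric, type: numeric}
  - {name: bp_systolic, block: anthropometric, type: numeric}
  - {name: bp_diastolic, block: anthropometric, type: numeric}
  - {name: ogtt_fasting, block: biochemistry, type: numeric}
  - {name: ogtt_1h, block: biochemistry, type: numeric}
  - {name: ogtt_2h, block: biochemistry, type: numeric}
  - {name: fasting_insulin, block: biochemistry, type: numeric}
  - {name: hba1c, block: biochemistry, type: numeric}
  - {name: fructosamine, block: biochemistry, type: numeric}
  - {name: leptin, block: biochemistry, type: numeric}
  - {name: cholesterol, block: biochemistry, type: numeric}
  - {name: hdl, block: biochemistry, type: numeric}
  - {name: ldl, block: biochemistry, type: numeric}
  - {name: vldl, block: biochemistry, type: numeric}
  - {name: triglycerides, block: biochemistry, type: numeric}
  - {name: n_pregnancies, block: history, type: numeric}
  - {name: n_abortions, block: history, type: numeric}
  - {name: n_deliveries, block: history, type: numeric}
  - {name: n_miscarriages, block: history, type: numeric}
  - {name: gdm_history, block: history, type: binary}
  - {name: pcos, block: history, type: binary}
  - {name: igt_history, block: history, type: binary}
  - {name: family_diabetes, block: history, type: binary}
  - {name: hypertension, block: history, type: binary}
  - {name: oc_pills, block: history, type: binary}
  - {name: smoking, block: history, type: binary}
  - {name: group_gdm, block: history, type: binary}
  - {name: fruits1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: fruits2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: vegetables1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: vegetables2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: meat1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: meat2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sousages1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sousages2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: fish1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: fish2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: dairy1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: dairy2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: bread1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: bread2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: cereals1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: cereals2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sweets1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sweets2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: pastry1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: pastry2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: types_food1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: types_food2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: soda1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: soda2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: coffee1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: coffee2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: juice1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: juice2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: walking1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: walking2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sport1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: sport2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: stairs1, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
  - {name: stairs2, block: questionnaire, type: ordinal, levels: [0, 1, 2]}
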