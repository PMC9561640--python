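# Default phenotype rules: an OR of lab clauses (evaluated on records inside the
# baseline window) and diagnosis-category lookups.  Comparators: >=, >, <, <=.
dyslipidemia:
  lab_clauses:
    - {analyte: TC,  comparator: ">=", threshold: 240}
    - {analyte: HDL, comparator: "<",  threshold: 40}
    - {analyte: LDL, comparator: ">=", threshold: 160}
    - {analyte: TG,  comparator: ">=", threshold: 200}
  diagnosis_categories: [dyslipidemia]
liver_disease:
  lab_clauses:
    - {analyte: AST, comparator: ">=", threshold: 120}
    - {analyte: ALT, comparator: ">=", threshold: 120}
  diagnosis_categories: [steatosis_of_liver, cirrhosis, hepatitis]
renal_disease:
  lab_clauses:
    - {analyte: SCR, comparator: ">", threshold: 1.4}
  diagnosis_categories: [renal_failure, chronic_kidney_disease]
  egfr_below: 60
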