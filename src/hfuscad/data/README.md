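# Packaged cohort summary tables

Study-level summary tables for the 45-animal cohort (7 WT and 7 KO mice on
standard diet, 16 WT and 15 KO mice on Western diet, scored at 24 weeks of
age), stored verbatim at printed precision.

- `table1_phenotype.csv` — per-group means and SDs of cumulative body-weight
  gain (g/week), cumulative energy intake (kcal/day/mouse), feed efficiency
  ratio (%), blood urea nitrogen and creatinine (mg/dL).
- `table3_cus_by_sss.csv` — joint counts over (group x CUS total 0-6 x SSS
  total 0-7); only nonzero cells are stored; counts sum to 45.
- `table4_hri_by_sss.csv` — per-(group, SSS total) hepatorenal-index mean,
  SD and range; single-animal cells store the single value.  The KO_WD
  SSS=3 cell prints a mean outside its own range and is stored verbatim with
  `inconsistent=1`; it is excluded from truncation-range checks downstream.
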