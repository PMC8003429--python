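# Italian national-average liver-transplant waiting list, 2012-2018.
# Fractions may be given either as fractions (wl_fraction) or percentages
# (wl_fraction_pct); months are calendar months of 30.4375 days.
name: italy_2012_2018
wl_size: 58
organs_per_year: 49
subgroups:
  meld_le20:
    median_wl_survival: 29.5
    median_time_to_lt: 12.8
    post_lt_5yr_survival_pct: 83
    wl_fraction_pct: 37
  meld_21_30:
    median_wl_survival: 6.7
    median_time_to_lt: 4.4
    post_lt_5yr_survival_pct: 81
    wl_fraction_pct: 13
  meld_gt30:
    median_wl_survival: 0.9
    median_time_to_lt: 0.7
    post_lt_5yr_survival_pct: 76
    wl_fraction_pct: 4
  hcc:
    median_wl_survival: 20.7
    median_time_to_lt: 9.5
    post_lt_5yr_survival_pct: 81
    wl_fraction_pct: 46
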