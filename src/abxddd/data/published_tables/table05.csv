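molecule,ddds,cost_inr,printed_ddd_share_pct,printed_cost_share_pct,printed_cost_per_ddd_inr
Ceftriaxone,88100000,11600000000,33.6,15.3,131.3
Amikacin,35300000,7300000000,13.5,9.7,207.3
Gentamicin,22800000,661200000,8.7,0.87,29.0
Ceftriaxone - sulbactam,17200000,5700000000,6.6,7.5,330.7
Cefotaxime,13800000,2500000000,5.3,3.2,177.6
all_other,85300000,48000000000,32.4,63.4,1705.5
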