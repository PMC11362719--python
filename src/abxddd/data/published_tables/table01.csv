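route,ddds,cost_inr,printed_ddd_share_pct,printed_cost_share_pct,printed_per_capita_cost_inr,printed_cost_per_ddd_inr
Injectable,262600000,75700000000,5.1,35.8,57.7,288.2
Oral,4860900000,135900000000,94.9,64.2,103.5,27.9
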