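route,public_ddds,private_ddds,public_cost_inr,private_cost_inr,printed_public_ddd_pct,printed_private_ddd_pct,printed_public_cost_pct,printed_private_cost_pct
Oral,110400000,167200000,500600000,4909500000,39.8,60.2,9.3,90.7
Injectable,2600000,5500000,167400000,2505300000,31.4,68.6,6.3,93.7
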