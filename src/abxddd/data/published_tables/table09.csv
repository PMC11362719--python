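aware,public_cost_inr,private_cost_inr,printed_public_cost_pct,printed_private_cost_pct
Access,27400000,266700000,9.3,90.7
Watch,111000000,1493100000,6.9,93.1
Reserve,4000000,163000000,2.4,97.6
Discouraged,25000000,582500000,4.1,95.9
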