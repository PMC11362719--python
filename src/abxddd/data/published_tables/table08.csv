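aware,public_ddds,public_did,private_ddds,private_did,printed_public_ddd_pct,printed_private_ddd_pct
Access,630000,0.049,1200000,0.096,34.0,66.0
Watch,1600000,0.129,3300000,0.259,33.3,66.7
Reserve,20000,0.002,70000,0.005,25.8,74.2
Discouraged,260000,0.021,1000000,0.079,20.8,79.2
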