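atc4,label,ddds,cost_inr,printed_ddd_share_pct,printed_cost_share_pct,printed_cost_per_ddd_inr
J01DD,Third generation cephalosporins,139700000,32000000000,53.2,42.3,229.2
J01GB,Other aminoglycosides,59600000,8400000000,22.7,11.2,141.6
J01CR,"Combinations of penicillin, incl. BLIs",24100000,9300000000,9.2,12.3,386.1
J01FF,Lincosamides,8800000,1500000000,3.3,2.0,173.2
J01MA,Fluoroquinolones,8500000,1800000000,3.2,2.4,213.6
other,All the other groups,21900000,22600000000,8.3,29.9,1662.8
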