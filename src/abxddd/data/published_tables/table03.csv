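atc3,label,ddds,cost_inr,printed_ddd_share_pct,printed_cost_share_pct,printed_cost_per_ddd_inr
J01D,Other beta-lactam antibacterials,145800000,45700000000,55.5,60.4,313.8
J01G,Aminoglycoside antibacterials,59600000,8400000000,22.7,11.2,141.7
J01C,"Beta-lactam antibacterials, penicillin",29300000,9600000000,11.2,12.7,328.3
J01F,"Macrolides, lincosamides and streptogramins",9500000,1700000000,3.6,2.3,182.9
J01M,Quinolone antibacterials,8500000,1800000000,3.2,2.4,213.6
other,All the other groups,9900000,8300000000,3.8,1.0,1194.5
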