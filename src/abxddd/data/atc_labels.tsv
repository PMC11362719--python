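prefix	level	label
J01A	3	Tetracyclines
J01AA	4	Tetracyclines
J01C	3	Beta-lactam antibacterials, penicillin
J01CA	4	Penicillin with extended spectrum
J01CE	4	Beta-lactamase sensitive penicillin
J01CF	4	Beta-lactamase resistant penicillin
J01CR	4	Combinations of penicillin, incl. BLIs
J01D	3	Other beta-lactam antibacterials
J01DB	4	First-generation cephalosporins
J01DC	4	Second-generation cephalosporins
J01DD	4	Third generation cephalosporins
J01DE	4	Fourth-generation cephalosporins
J01DF	4	Monobactams
J01DH	4	Carbapenems
J01F	3	Macrolides, lincosamides and streptogramins
J01FA	4	Macrolides
J01FF	4	Lincosamides
J01G	3	Aminoglycoside antibacterials
J01GA	4	Streptomycins
J01GB	4	Other aminoglycosides
J01M	3	Quinolone antibacterials
J01MA	4	Fluoroquinolones
J01R	3	Combinations of antibacterials
J01RA	4	Combinations of antibacterials
J01X	3	Other antibacterials
J01XA	4	Glycopeptide antibacterials
J01XB	4	Polymyxins
J01XX	4	Other antibacterials
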