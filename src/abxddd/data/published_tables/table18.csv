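molecule,private_ddds,public_ddds,private_cost_inr,public_cost_inr,printed_private_ddd_pct,printed_public_ddd_pct,printed_private_cost_pct,printed_public_cost_pct
Amoxicillin - clavulanic acid,239600,95500,114490300,8974100,71.5,28.5,92.7,7.3
Ampicillin,58900,79600,13160900,5616000,42.5,57.5,70.1,29.9
Azithromycin,28700,23000,4873800,1292700,55.6,44.4,79.0,21.0
Aztreonam,600,1400,1905000,2168100,31.3,68.7,46.8,53.2
Benzylpenicillin,0,161400,0,8418600,0.0,100.0,0.0,100.0
Cefoperazone - sulbactam,186900,264600,392464600,25035100,41.4,58.6,94.0,6.0
Cefotaxime,531800,691700,84675900,34730600,43.5,56.5,70.9,29.1
Ceftazidime,13500,2100,11609500,336200,86.6,13.4,97.2,2.8
Ceftriaxone,1754700,475000,224424100,12097300,78.7,21.3,94.9,5.1
Cefuroxime,223300,130800,152998800,8634900,63.1,36.9,94.7,5.3
Ciprofloxacin,77600,94200,6025800,3638300,45.2,54.8,62.4,37.6
Cloxacillin,0,19100,0,750500,0.0,100.0,0.0,100.0
Gentamicin,433600,271600,12327400,3687300,61.5,38.5,77.0,23.0
Levofloxacin,140500,13200,22153600,370700,91.4,8.6,98.4,1.6
Linezolid,58700,23800,63933000,3317000,71.2,28.8,95.1,4.9
Meropenem,120000,13000,570866800,4662400,90.2,9.8,99.2,0.8
Ofloxacin,107800,21300,27120600,539800,83.5,16.5,98.0,2.0
Piperacillin -tazobactam,196100,170900,224435300,42797500,53.4,46.6,84.0,16.0
Teicoplanin,33400,1000,78317000,327000,97.2,2.8,99.6,0.4
Tigecycline,1900,200,11584900,237200,88.6,11.4,98.0,2.0
Vancomycin,10100,21700,11205800,3222100,31.8,68.2,77.7,22.3
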