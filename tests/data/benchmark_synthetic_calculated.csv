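# SYNTHETIC benchmark fixture: a spectral-library-calculated MRM transition
# table for well-characterized small molecules (amino acids, TCA-cycle
# intermediates, caffeine, BMAA, a lysophospholipid). Values are plausible
# constructions, not real library output; the file exists to exercise the
# table-comparison metrics together with its experimental counterpart.
compound_id,polarity,precursor_mz,product_mz,ce_eV,role,rank
glutamic_acid,positive,148.0604,84.0000,20,quantifier,1
glutamic_acid,positive,148.0604,130.0000,12,qualifier,2
arginine,positive,175.1190,70.0000,24,quantifier,1
arginine,positive,175.1190,60.0000,18,qualifier,2
caffeine,positive,195.0877,138.0000,20,quantifier,1
caffeine,positive,195.0877,42.0000,36,qualifier,2
bmaa,positive,119.0815,44.0000,10,quantifier,1
bmaa,positive,119.0815,102.1000,8,qualifier,2
lysope_13_0,positive,426.2615,216.0630,14,quantifier,1
lysope_13_0,positive,426.2615,104.1070,20,qualifier,2
malate,negative,133.0142,115.0030,12,quantifier,1
malate,negative,133.0142,73.0290,18,qualifier,2
citrate,negative,191.0197,111.0080,12,quantifier,1
citrate,negative,191.0197,87.0080,18,qualifier,2
succinate,negative,117.0193,73.0290,12,quantifier,1
succinate,negative,117.0193,99.0080,10,qualifier,2
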