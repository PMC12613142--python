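# SYNTHETIC benchmark fixture: instrument-optimized counterpart of
# benchmark_synthetic_calculated.csv (same provenance caveats). Differences
# are deliberate: CEs shifted by a few eV, the malate qualifier at m/z 71
# instead of 73, and the LysoPE 13:0 quantifier/qualifier roles
# interchanged.
compound_id,polarity,precursor_mz,product_mz,ce_eV,role,rank
glutamic_acid,positive,148.0604,84.0000,19,quantifier,1
glutamic_acid,positive,148.0604,130.0000,10,qualifier,2
arginine,positive,175.1190,70.0000,26,quantifier,1
arginine,positive,175.1190,60.0000,15,qualifier,2
caffeine,positive,195.0877,138.0000,22,quantifier,1
caffeine,positive,195.0877,42.0000,40,qualifier,2
bmaa,positive,119.0815,44.0000,15,quantifier,1
bmaa,positive,119.0815,102.1000,9,qualifier,2
lysope_13_0,positive,426.2615,104.1070,22,quantifier,1
lysope_13_0,positive,426.2615,216.0630,15,qualifier,2
malate,negative,133.0142,115.0030,10,quantifier,1
malate,negative,133.0142,71.0130,20,qualifier,2
citrate,negative,191.0197,111.0080,14,quantifier,1
citrate,negative,191.0197,87.0080,20,qualifier,2
succinate,negative,117.0193,73.0290,14,quantifier,1
succinate,negative,117.0193,99.0080,12,qualifier,2
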