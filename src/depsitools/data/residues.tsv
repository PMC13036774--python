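# In-chain residue formulas (monomer minus water).
# flags: semicolon-separated markers; "ureido" marks residues with a ureido
# group that eliminates isocyanic acid (HNCO) under CID (citrulline).
# columns: name	formula	flags
Gly	C2H3NO
Ala	C3H5NO
Ser	C3H5NO2
Pro	C5H7NO
Val	C5H9NO
Thr	C4H7NO2
Cys	C3H5NOS
Leu	C6H11NO
Ile	C6H11NO
Asn	C4H6N2O2
Asp	C4H5NO3
Gln	C5H8N2O2
Lys	C6H12N2O
Glu	C5H7NO4
Met	C5H9NOS
His	C6H7N3O
Phe	C9H9NO
Arg	C6H12N4O
Tyr	C9H9NO2
Trp	C11H10N2O
Orn	C5H10N2O
OHPro	C5H7NO2
Cit	C6H11N3O2	ureido
OHTrp	C11H10N2O2
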