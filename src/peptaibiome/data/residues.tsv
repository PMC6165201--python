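# Peptaibol residue library: residue (amino acid minus water) elemental compositions.
# Amino-alcohol residues (code ending in "ol") store the reduced-carboxyl composition
# (parent residue - O + 2H) and may only occupy the C-terminal position.
# Class tokens Lxx/Vxx/Lxxol stand for {Leu,Ile}/{Val,Iva}/{Leuol,Ileol}; members of one
# class are isobaric, so class tokens carry a well-defined mass.
code	formula	iso_class
Gly	C2H3NO	Gly
Ala	C3H5NO	Ala
Ser	C3H5NO2	Ser
Pro	C5H7NO	Pro
Val	C5H9NO	Vxx
Thr	C4H7NO2	Thr
Cys	C3H5NOS	Cys
Leu	C6H11NO	Lxx
Ile	C6H11NO	Lxx
Asn	C4H6N2O2	Asn
Asp	C4H5NO3	Asp
Gln	C5H8N2O2	Gln
Lys	C6H12N2O	Lys
Glu	C5H7NO3	Glu
Met	C5H9NOS	Met
His	C6H7N3O	His
Phe	C9H9NO	Phe
Arg	C6H12N4O	Arg
Tyr	C9H9NO2	Tyr
Trp	C11H10N2O	Trp
Aib	C4H7NO	Aib
Iva	C5H9NO	Vxx
Leuol	C6H13N	Lxxol
Ileol	C6H13N	Lxxol
Valol	C5H11N	Valol
Pheol	C9H11N	Pheol
Trpol	C11H12N2	Trpol
Tyrol	C9H11NO	Tyrol
Alaol	C3H7N	Alaol
Prool	C5H9N	Prool
Lxx	C6H11NO	Lxx
Vxx	C5H9NO	Vxx
Lxxol	C6H13N	Lxxol
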