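# Expected relations of every study compound to the packaged known-peptaibol database
# and to its positional isomers within the run, transcribed from the per-compound
# similarity annotations of the study tables.  Exchange records are written at
# isobaric-class resolution as pos:DbClass>QueryClass, ';'-separated, sorted by
# position.  relation is one of: identical, exchanges, isomer_of (isomer_of rows name
# another compound of the same run; at class resolution these pairs are
# indistinguishable, so either identical_by_class or positional_isomer is accepted).
# Rows marked [corrected] deviate from the printed lists where the source tables are
# internally inconsistent; the stored reading is the one consistent with the
# reconstructed database (see package docs).
query	target	relation	exchanges
Pept-Ia	Trikoningin KA V	exchanges	5:Lxx>Vxx;16:Lxx>Vxx
Pept-Ia	Tricholongin LBII	exchanges	3:Phe>Ala;5:Aib>Vxx
Pept-Ia	Tricholongin LBIV	exchanges	3:Phe>Ala;5:Aib>Vxx
Pept-Ia	Tricholongin BII	exchanges	3:Phe>Ala;5:Aib>Vxx
Pept-Ib	Trikoningin KA V	exchanges	5:Lxx>Vxx
Pept-Ib	Pept-IIb	isomer_of
Pept-Ib	Pept-IIIb	isomer_of
Pept-Ib	Pept-IVb	isomer_of
Pept-IIa	Trikoningin KA V	exchanges	16:Lxx>Vxx
Pept-IIa	Tricholongin LBII	exchanges	3:Phe>Ala;5:Aib>Lxx
Pept-IIa	Tricholongin LBIV	exchanges	3:Phe>Ala;5:Aib>Lxx
Pept-IIa	Tricholongin BII	exchanges	3:Phe>Ala;5:Aib>Lxx
Pept-IIa	Trichostrigocin TSG-A	exchanges	2:Ala>Gly;3:Aib>Ala
Pept-IIa	Trichostrigocin TSG-B	exchanges	2:Ala>Gly;3:Aib>Ala
Pept-IIa	Pept-IIIa	isomer_of
Pept-IIa	Pept-IVa	isomer_of
Pept-IIa	Pept-Va	isomer_of
Pept-IIa	Pept-VIa	isomer_of
Pept-IIa	Pept-VIIIa	isomer_of
Pept-IIb	Pept-Ib	isomer_of
Pept-IIb	Pept-IIIb	isomer_of
Pept-IIb	Pept-IVb	isomer_of
Pept-IIIa	Pept-IIa	isomer_of
Pept-IIIa	Pept-IVa	isomer_of
Pept-IIIa	Pept-Va	isomer_of
Pept-IIIa	Pept-VIa	isomer_of
Pept-IIIa	Pept-VIIIa	isomer_of
Pept-IIIb	Pept-Ib	isomer_of
Pept-IIIb	Pept-IIb	isomer_of
Pept-IIIb	Pept-IVb	isomer_of
Pept-IVa	Pept-IIa	isomer_of
Pept-IVa	Pept-IIIa	isomer_of
Pept-IVa	Pept-Va	isomer_of
Pept-IVa	Pept-VIa	isomer_of
Pept-IVa	Pept-VIIIa	isomer_of
Pept-IVb	Pept-Ib	isomer_of
Pept-IVb	Pept-IIb	isomer_of
Pept-IVb	Pept-IIIb	isomer_of
Pept-Va	Pept-IIa	isomer_of
Pept-Va	Pept-IIIa	isomer_of
Pept-Va	Pept-IVa	isomer_of
Pept-Va	Pept-VIa	isomer_of
Pept-Va	Pept-VIIIa	isomer_of
Pept-Vb	Trikoningin KA V	identical
Pept-Vb	Pept-VIb	isomer_of
Pept-Vb	Pept-VII	isomer_of
Pept-Vb	Pept-VIIIb	isomer_of
Pept-VIa	Pept-IIa	isomer_of
Pept-VIa	Pept-IIIa	isomer_of
Pept-VIa	Pept-IVa	isomer_of
Pept-VIa	Pept-Va	isomer_of
Pept-VIa	Pept-VIIIa	isomer_of
Pept-VIb	Pept-Vb	isomer_of
Pept-VIb	Pept-VII	isomer_of
Pept-VIb	Pept-VIIIb	isomer_of
Pept-VII	Pept-Vb	isomer_of
Pept-VII	Pept-VIb	isomer_of
Pept-VII	Pept-VIIIb	isomer_of
Pept-VIIIa	Pept-IIa	isomer_of
Pept-VIIIa	Pept-IIIa	isomer_of
Pept-VIIIa	Pept-IVa	isomer_of
Pept-VIIIa	Pept-Va	isomer_of
Pept-VIIIa	Pept-VIa	isomer_of
Pept-VIIIb	Pept-Vb	isomer_of
Pept-VIIIb	Pept-VIb	isomer_of
Pept-VIIIb	Pept-VII	isomer_of
Pept-IX	Tricholongin LBIII	exchanges	3:Phe>Ala;5:Aib>Lxx;16:Vxx>Lxx
Pept-X	Trikoningin KA V	exchanges	2:Gly>Ala
Pept-X	Trichostrigocin TSG-A	exchanges	3:Aib>Ala;16:Vxx>Lxx
Pept-X	Trichostrigocin TSG-B	exchanges	3:Aib>Ala;16:Vxx>Lxx
Pept-X	Trichorzianin TA IIIb	exchanges	5:Aib>Lxx;19:Trpol>Lxxol
Pept-X	Trichorzianin TA IIIc	exchanges	5:Aib>Lxx;19:Trpol>Lxxol
Pept-X	Trichorzianin TA VIb	exchanges	5:Aib>Lxx;19:Pheol>Lxxol
Pept-X	Trichorzianin TA IVb	exchanges	5:Vxx>Lxx;19:Trpol>Lxxol
Pept-X	Trichorzianin TA VII	exchanges	5:Vxx>Lxx;19:Pheol>Lxxol
Pept-X	Trichorzianin TAP-14a	exchanges	5:Aib>Lxx;19:Pheol>Lxxol	[corrected]
Pept-X	Trichorzianin TB IIIc	exchanges	5:Aib>Lxx;18:Glu>Gln;19:Trpol>Lxxol	[corrected]
Pept-X	Trichorzianin TB IVb	exchanges	5:Vxx>Lxx;18:Glu>Gln;19:Trpol>Lxxol	[corrected]
Pept-X	Trichorzianin TB VIb	exchanges	5:Aib>Lxx;18:Glu>Gln;19:Pheol>Lxxol	[corrected]
Pept-X	Trichorzianin TB VII	exchanges	5:Vxx>Lxx;18:Glu>Gln;19:Pheol>Lxxol	[corrected]
Pept-X	Pept-XI	isomer_of
Pept-X	Pept-XII	isomer_of
Pept-XI	Pept-X	isomer_of
Pept-XI	Pept-XII	isomer_of
Pept-XII	Pept-X	isomer_of
Pept-XII	Pept-XI	isomer_of
Koningiopsin Ia	Trichorzianin TAP-14b	exchanges	19:Pheol>Lxxol
Koningiopsin Ib	Trichorzianin TA IVb	exchanges	19:Trpol>Lxxol
Koningiopsin Ib	Trichorzianin TA VII	exchanges	19:Pheol>Lxxol
Koningiopsin IIa	Trichorzianin TA IVb	exchanges	5:Vxx>Aib;9:Aib>Lxx;16:Lxx>Vxx;19:Trpol>Lxxol	[corrected]
Koningiopsin IIa	Trichostrigocin TSG-A	exchanges	3:Aib>Ala;5:Lxx>Aib;9:Aib>Lxx	[corrected]
Koningiopsin IIa	Trichostrigocin TSG-B	exchanges	3:Aib>Ala;5:Lxx>Aib;9:Aib>Lxx	[corrected]
Koningiopsin IIb	Trichorzianin TA IIIb	exchanges	10:Ser>Vxx;19:Trpol>Lxxol
Koningiopsin IIb	Trichorzianin TA IIIc	exchanges	10:Ser>Vxx;19:Trpol>Lxxol
Koningiopsin IIb	Trichorzianin TA VIb	exchanges	10:Ser>Vxx;19:Pheol>Lxxol
Koningiopsin IIb	Trichorzianin TAP-14a	exchanges	10:Ser>Vxx;19:Pheol>Lxxol
Koningiopsin IIIa	Trichorzianin TAP-14b	exchanges	5:Vxx>Ala;9:Aib>Lxx;18:Gln>Glu;19:Pheol>Lxxol
Koningiopsin IIIa	Trichorzianin TB IIIc	exchanges	5:Aib>Ala;9:Aib>Lxx;16:Lxx>Vxx;19:Trpol>Lxxol
Koningiopsin IIIa	Trichorzianin TB IVb	exchanges	5:Vxx>Ala;9:Aib>Lxx;16:Lxx>Vxx;19:Trpol>Lxxol
Koningiopsin IIIa	Trichorzianin TB VIb	exchanges	5:Aib>Ala;9:Aib>Lxx;16:Lxx>Vxx;19:Pheol>Lxxol
Koningiopsin IIIa	Trichorzianin TB VII	exchanges	5:Vxx>Ala;9:Aib>Lxx;16:Lxx>Vxx;19:Pheol>Lxxol
Koningiopsin IIIa	Trichostrigocin TSG-A	exchanges	3:Aib>Ala;5:Lxx>Ala;9:Aib>Lxx;18:Gln>Glu
Koningiopsin IIIa	Trichostrigocin TSG-B	exchanges	3:Aib>Ala;5:Lxx>Ala;9:Aib>Lxx;18:Gln>Glu
Koningiopsin IIIb	Trichorzianin TAP-14b	exchanges	5:Vxx>Aib;10:Ser>Vxx;19:Pheol>Lxxol	[corrected]
Koningiopsin IV	Trichorzianin TA IIIb	exchanges	9:Aib>Lxx;19:Trpol>Lxxol
Koningiopsin IV	Trichorzianin TA IIIc	exchanges	9:Aib>Lxx;19:Trpol>Lxxol
Koningiopsin IV	Trichorzianin TA VIb	exchanges	9:Aib>Lxx;19:Pheol>Lxxol
Koningiopsin IV	Trichorzianin TAP-14a	exchanges	9:Aib>Lxx;19:Pheol>Lxxol
Koningiopsin IV	Koningiopsin Va	isomer_of
Koningiopsin Va	Koningiopsin IV	isomer_of
Koningiopsin Vb	Trichorzianin TB IIIc	exchanges	9:Aib>Lxx;19:Trpol>Lxxol
Koningiopsin Vb	Trichorzianin TB VIb	exchanges	9:Aib>Lxx;19:Pheol>Lxxol
Koningiopsin VIa	Trichorzianin TA IIIb	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Trpol>Lxxol
Koningiopsin VIa	Trichorzianin TA IIIc	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Trpol>Lxxol
Koningiopsin VIa	Trichorzianin TA VIb	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Pheol>Lxxol
Koningiopsin VIa	Trichorzianin TAP-14a	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Pheol>Lxxol
Koningiopsin VIb	Trichorzianin TB IIIc	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Trpol>Lxxol
Koningiopsin VIb	Trichorzianin TB VIb	exchanges	9:Aib>Lxx;10:Ser>Ala;19:Pheol>Lxxol
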