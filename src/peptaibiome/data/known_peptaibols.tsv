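# Known 19-residue peptaibols used for similarity annotation.  This is a packaged
# comparison fixture: sequences are reconstructed from the trikoningin, tricholongin,
# trichostrigocin and trichorzianin residue exchanges reported for the compounds of
# the two study strains; it is not a copy of any external database.  Where only the
# isobaric class of a residue is determined, a representative member is stored
# (comparison runs at class resolution).
name	sequence	source_ref
Trikoningin KA V	Ac-Aib-Gly-Ala-Aib-Ile-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Leuol	trikoningins (T. koningii)
Tricholongin LBII	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	tricholongins (T. longibrachiatum / T. strigosum)
Tricholongin LBIII	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ala-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	tricholongins (T. longibrachiatum / T. strigosum)
Tricholongin LBIV	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Ile-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	tricholongins (T. longibrachiatum / T. strigosum)
Tricholongin BII	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	tricholongins (T. longibrachiatum)
Trichostrigocin TSG-A	Ac-Aib-Ala-Aib-Aib-Leu-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	trichostrigocins (T. strigosum)
Trichostrigocin TSG-B	Ac-Aib-Ala-Aib-Aib-Ile-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Leuol	trichostrigocins (T. strigosum)
Trichorzianin TA IIIb	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Trpol	trichorzianins A (T. atroviride)
Trichorzianin TA IIIc	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Leu-Gln-Gln-Trpol	trichorzianins A (T. atroviride)
Trichorzianin TA IVb	Ac-Aib-Ala-Ala-Aib-Iva-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Trpol	trichorzianins A (T. atroviride)
Trichorzianin TA VIb	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Pheol	trichorzianins A (T. atroviride)
Trichorzianin TA VII	Ac-Aib-Ala-Ala-Aib-Iva-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Pheol	trichorzianins A (T. atroviride)
Trichorzianin TAP-14a	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Pheol	trichorzianins A (T. atroviride P.)
Trichorzianin TAP-14b	Ac-Aib-Ala-Ala-Aib-Iva-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Val-Gln-Gln-Pheol	trichorzianins A (T. atroviride P.)
Trichorzianin TB IIIc	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Glu-Trpol	trichorzianins B (T. atroviride)
Trichorzianin TB IVb	Ac-Aib-Ala-Ala-Aib-Iva-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Glu-Trpol	trichorzianins B (T. atroviride)
Trichorzianin TB VIb	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Glu-Pheol	trichorzianins B (T. atroviride)
Trichorzianin TB VII	Ac-Aib-Ala-Ala-Aib-Iva-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Glu-Pheol	trichorzianins B (T. atroviride)
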