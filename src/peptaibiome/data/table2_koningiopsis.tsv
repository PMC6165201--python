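# Characteristic ions, retention times, relative areas and de-novo sequences of the
# 11 Koningiopsin compounds of the T. koningiopsis strain run.  Conventions as in
# table1_gamsii.tsv.
peptide	M	m_na	m_2na	b12	y7	rt_min	area_percent	sequence
Koningiopsin Ia	1875.5	1898.5	960.75	1121.9	754.5	53.121	0.91	Ac-Aib-Ala-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Koningiopsin Ib	1889.5	1912.5	967.75	1121.5	768.5	54.267	5.96	Ac-Aib-Ala-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Koningiopsin IIa	1890.5	1913.5	968.25	1136.7	754.5	54.69	8.13	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Koningiopsin IIb	1889.6	1912.6	967.8	1120.8	768.6	55.513	2.88	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Vxx-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Koningiopsin IIIa	1891.6	1914.6	968.8	1122.7	755.6	55.593	0.97	Ac-Aib-Ala-Ala-Aib-Ala-Gln-Aib-Aib-Lxx-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Glu-Lxxol
Koningiopsin IIIb	1873.6	1896.6	959.8	1120.8	754.5	55.936	2.03	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Aib-Vxx-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Koningiopsin IV	1903.6	1926.6	974.8	1136.7	768.6	56.317	12.27	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Koningiopsin Va	1903.6	1926.6	974.8	1136.8	768.6	56.739	47.94	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Koningiopsin Vb	1905.6	1928.6	975.8	1136.8	769.6	57.463	5.95	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Glu-Lxxol
Koningiopsin VIa	1888.6	1911.6	967.3	1120.7	768.6	57.825	11.54	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ala-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Koningiopsin VIb	1888.7	1911.7	967.35	1120.9	769.5	58.448	1.41	Ac-Aib-Ala-Ala-Aib-Aib-Gln-Aib-Aib-Lxx-Ala-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Glu-Lxxol
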