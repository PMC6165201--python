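# Characteristic ions, retention times, relative areas and de-novo sequences of the
# 19 peptaibol compounds of the T. gamsii strain run.  Masses are observed ion-trap
# values (unit resolution).  Sequences use isobaric class tokens (Lxx, Vxx, Lxxol)
# where MS cannot discriminate members.
# Pept-X: the y7, rt and area values were not legible in the source table and are
# reconstructed: y7 768.4 (Lxx16/Gln18 family follows from the sequence), rt 58.10 min
# (elution order IX < X < XI), area 0.00% (the other 18 percentages sum to 100.00).
# Pept-IVa: R5 corrected to Lxx (its printed b12 1122.5 and its positional-isomer
# grouping with Pept-IIa both require Lxx5).
peptide	M	m_na	m_2na	b12	y7	rt_min	area_percent	sequence
Pept-Ia	1861.1	1884.1	953.55	1108.5	754.4	50.504	0.28	Ac-Aib-Gly-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-Ib	1876.2	1899.2	961.1	1108.5	768.4	51.073	1.51	Ac-Aib-Gly-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-IIa	1876.1	1899.1	961.05	1122.5	754.4	51.175	1.66	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-IIb	1875.2	1898.2	960.6	1108.5	768.4	52.316	1.99	Ac-Aib-Gly-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-IIIa	1876.2	1899.2	961.1	1122.5	754.4	53.005	0.56	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-IIIb	1875.3	1898.3	960.65	1108.5	768.4	53.292	2.96	Ac-Aib-Gly-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-IVa	1875.2	1898.2	960.6	1122.5	754.4	53.555	3.70	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-IVb	1875.2	1898.2	960.6	1108.5	768.4	53.996	9.21	Ac-Aib-Gly-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-Va	1876.2	1899.2	961.1	1122.5	754.4	54.776	4.49	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-Vb	1890.2	1913.2	968.1	1122.5	768.4	55.313	5.41	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-VIa	1876.2	1899.2	961.1	1122.5	754.4	55.617	0.84	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-VIb	1890.2	1913.2	968.1	1122.5	768.4	55.798	23.32	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-VII	1889.3	1912.3	967.65	1122.5	768.4	56.403	4.16	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-VIIIa	1874.2	1897.2	960.1	1122.5	754.4	56.806	0.49	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol
Pept-VIIIb	1890.2	1913.2	968.1	1122.5	768.4	56.826	27.99	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-IX	1874.5	1897.5	960.25	1106.5	768.4	57.554	5.92	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ala-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-X	1904.2	1927.2	975.1	1136.4	768.4	58.10	0.00	Ac-Aib-Ala-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-XI	1903.3	1926.3	974.65	1136.5	768.4	58.602	4.82	Ac-Aib-Ala-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
Pept-XII	1904.2	1927.2	975.1	1136.6	768.4	59.264	0.69	Ac-Aib-Ala-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol
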