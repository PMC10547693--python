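gene_id	synonyms	chrom	strand	span_start	span_end	transcript_length	protein_length	exon_count
Ma1	Sobic.006G057866,SORBI_3006G057866,Sb06g014570,PRR37	Chr06	+	40304883	40316799	4373	739	8
Ma2	Sobic.002G302700,SORBI_3002G302700	Chr02	+	67882606	67888127	1677	401	11
Ma3	Sobic.001G394400,SORBI_3001G394400,Sb01g037340,PHYB	Chr01	-	68034103	68043358	5508	1178	4
Ma5	Sobic.001G087100,SORBI_3001G087100,Sb01g007850,PHYC	Chr01	-	6748036	6753421	4372	1135	4
Ma6	Sobic.006G004400,SORBI_3006G004400,Sb06g000570,GHD7	Chr06	+	697459	700101	741	246	3
Dw1	Sobic.009G229800,SORBI_3009G229800	Chr09	+	57038653	57041166	1533	528	2
Dw2	Sobic.006G067700,SORBI_3006G067700,Sb06g015430,KIPK	Chr06	-	42803037	42807520	4145	809	2
Dw3	Sobic.007G163800,SORBI_3007G163800,Sb07g023730,PGP1,ABCB1	Chr07	-	59821905	59829921	5304	1541	5
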