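taxon	depth	total_samples	ow_samples	nw_samples	jc_full_mito_pct	divergence_date_mya
Anser albifrons	Population	8	3	5	0.66	0.327
Spatula clypeata	Population	9	5	4	0.35	0.029
Mareca penelope/M. americana	Species	16	8	8	1.43	0.496
Anas platyrhynchos	Population	12	5	7	0.34	0.239
Anas acuta	Population	10	5	5	0.18	0.087
Anas c. crecca/A. c. carolinensis	Subspecies	14	7	7	3.19	1.770
Aythya marila	Population	10	5	5	1.32	0.629
Somateria spectabilis	Population	7	2	5	0.25	0.140
Somateria mollissima	Population	10	5	5	0.33	0.157
Histrionicus histrionicus	Population	8	6	2	0.05	0.026
Melanitta americana	Population	6	2	4	0.12	0.048
Clangula hyemalis	Population	13	7	6	0.11	0.031
Mergus merganser merganser/M. m. americanus	Subspecies	10	6	4	0.48	0.263
Lagopus lagopus koreni/L. l. alascensis	Subspecies	10	5	5	0.30	0.113
Pluvialis fulva/P. dominica	Species	8	4	4	3.21	1.563
Numenius phaeopus variegatus/N. p. hudsonicus	Subspecies	15	8	7	2.70	1.078
Arenaria interpres/A. melanocephala	Species	9	5	4	3.62	1.511
Calidris alpina arcticola/C. a. pacifica	Subspecies	8	3	5	2.45	0.896
Gallinago gallinago/G. delicata	Species	10	5	5	1.97	1.081
Tringa brevipes/T. incana	Species	16	8	8	3.82	1.837
Tringa nebularia/T. melanoleuca	Species	10	5	5	1.73	0.700
Uria aalge	Population	10	5	5	0.46	0.160
Uria lomvia	Population	10	5	5	1.99	1.026
Larus canus/L. brachyrhynchus	Species	10	5	5	0.89	0.407
Larus argentatus vegae/L. a. smithsonianus	Subspecies	10	5	5	0.41	0.154
Larus hyperboreus	Population	10	5	5	0.32	0.140
Gavia stellata	Population	10	5	5	0.29	0.000
Picoides tridactylus/P. fasciatus	Species	8	3	5	2.89	0.868
Pica pica/P. hudsonia	Species	15	8	7	3.00	1.348
Corvus corax	Population	17	7	10	0.56	0.139
Phylloscopus examinandus/P. borealis	Species	10	5	5	2.74	0.814
Phylloscopus borealis borealis/P. b. kennicotti	Subspecies	15	5	10	2.53	0.741
Cyanecula svecica	Population	16	8	8	0.16	0.048
Motacilla tschutschensis tschutschensis/M. t. simillima	Subspecies	10	5	5	0.69	0.369
Anthus rubescens japonicus/A. r. pacificus	Subspecies	10	5	5	2.70	1.293
Pinicola enucleator tschutschensis/P. e. flammula	Subspecies	13	6	7	2.06	0.938
Leucosticte arctoa/L. tephrocotis	Species	24	5	19	1.31	0.524
Calcarius lapponicus coloratus/C. l. alascensis	Subspecies	7	2	5	2.27	0.638
Plectrophenax nivalis/P. hyperboreus	Species	8	4	4	0.43	0.263
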