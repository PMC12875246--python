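taxon	depth	fst	sd	p
Anser albifrons	Population	-0.092	0.015	0.313
Spatula clypeata	Population	-0.092	0.016	0.396
Mareca penelope/M. americana	Species	0.482	0.005	0.035
Anas platyrhynchos	Population	0.053	0.012	0.183
Anas acuta	Population	-0.026	0.016	0.396
Anas c. crecca/A. c. carolinensis	Subspecies	0.793	0.014	0.002
Aythya marila	Population	0.340	0.004	0.013
Somateria spectabilis	Population	0.045	0.014	0.238
Somateria mollissima	Population	0.116	0.011	0.169
Histrionicus histrionicus	Population	0.090	0.016	0.425
Melanitta americana	Population	-0.057	0.012	0.465
Clangula hyemalis	Population	-0.015	0.016	0.550
Mergus merganser merganser/M. m. americanus	Subspecies	-0.040	0.009	0.897
Lagopus lagopus koreni/L. l. alascensis	Subspecies	-0.034	0.010	0.908
Pluvialis fulva/P. dominica	Species	0.967	0.006	0.029
Numenius phaeopus	Population	-0.106	0.007	0.941
Arenaria interpres/A. melanocephala	Species	0.886	0.003	0.020
Calidris alpina arcticola/C. a. pacifica	Subspecies	-0.010	0.014	0.340
Gallinago gallinago/G. delicata	Species	-0.138	0.000	0.999
Tringa brevipes/T. incana	Species	0.958	0.000	0.000
Tringa nebularia/T. melanoleuca	Species	0.401	0.005	0.027
Uria aalge	Population	0.187	0.006	0.045
Uria lomvia	Population	0.020	0.013	0.309
Larus canus/L. brachyrhynchus	Species	0.137	0.010	0.165
Larus argentatus vegae/L. a. smithsonianus	Subspecies	-0.042	0.000	0.999
Larus hyperboreus	Population	-0.028	0.016	0.536
Gavia stellata	Population	0.043	0.000	0.999
Picoides tridactylus/P. fasciatus	Species	0.627	0.003	0.014
Pica pica/P. hudsonia	Species	0.653	0.000	0.000
Corvus corax	Population	0.122	0.001	0.001
Phylloscopus examinandus/P. borealis	Species	0.158	0.013	0.254
Phylloscopus borealis borealis/P. b. kennicotti	Subspecies	-0.030	0.018	0.611
Cyanecula svecica	Population	-0.022	0.009	0.832
Motacilla tschutschensis tschutschensis/M. t. simillima	Subspecies	0.098	0.012	0.188
Anthus rubescens japonicus/A. r. pacificus	Subspecies	0.349	0.010	0.005
Pinicola enucleator tschutschensis/P. e. flammula	Subspecies	0.095	0.011	0.107
Leucosticte arctoa/L. tephrocotis	Species	0.463	0.004	0.016
Calcarius lapponicus coloratus/C. l. alascensis	Subspecies	0.270	0.009	0.132
Plectrophenax nivalis/P. hyperboreus	Species	0.023	0.013	0.524
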