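taxon	coverage_sanger	coverage_illumina	sanger_pi	illumina_pi
Overall	1-2	270.7	0.025	0.015
Anas c. crecca/A. c. carolinensis	1-2	288.7	0.046	0.018
Mareca penelope/M. americana	1-2	270.6	0.012	0.01
Clangula hyemalis (Eurasia/N. American)	1-2	496.8	0.001	0.001
Luscinia svecica (Eurasia/N. America)	1-2	204.6	0.003	0.001
Numenius phaeopus (Eurasia/N. America)	1-2	213.4	0.024	0.019
Pica pica/P. hudsonia	1-2	89.6	0.037	0.018
Pinicola enucleator kamtschatkensis/P. e. flammula	1-2	378.6	0.039	0.026
Tringa brevipes/T. incana	1-2	222.9	0.04	0.028
Averages		270.7	0.025	0.015
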