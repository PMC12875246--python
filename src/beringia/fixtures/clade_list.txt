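Anas c. crecca/A. c. carolinensis
Mareca penelope/M. americana
Calidris alpina arcticola/C. a. pacifica
Gallinago gallinago/G. delicata
Corvus corax
Larus canus/L. brachyrhynchus
Numenius phaeopus
Anthus rubescens japonicus/A. r. pacificus
Pinicola enucleator tschutschensis/P. e. flammula
Calcarius lapponicus coloratus/C. l. alascensis
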