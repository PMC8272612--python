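# Default term-extraction patterns (50), Penn Treebank symbols, 1-4 tags.
# Symbol classes: NN matches NN|NNS, NP matches NNP|NNPS, JJ matches
# JJ|JJR|JJS, RB matches RB|RBR|RBS; any other symbol matches its exact tag.
NN
NP
JJ
VBG
NN NN
JJ NN
NP NP
NP NN
NN NP
JJ NP
VBG NN
VBN NN
NN VBG
JJ JJ
JJ VBG
NP VBG
NN NN NN
JJ NN NN
JJ JJ NN
NP NP NP
NN NP NP
JJ NP NP
NP NN NN
NN NN NP
JJ NN NP
VBG NN NN
VBN NN NN
NN VBG NN
NN IN NN
NN IN NP
NP IN NN
NN CC NN
RB JJ NN
NN NN NN NN
JJ NN NN NN
JJ JJ NN NN
NN NN NN NP
NP NP NP NP
NN NP NP NP
JJ NP NP NP
NP NN NN NN
NN IN NN NN
NN NN IN NN
NN IN JJ NN
JJ NN IN NN
NN VBD NN NN
NN VBZ NN NN
VBG NN NN NN
VBN NN NN NN
NN CC NN NN
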