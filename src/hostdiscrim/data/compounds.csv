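name,formula,pathway
L-phenylalanine,C9H11NO2,phenylalanine
L-tyrosine,C9H11NO3,tyrosine
L-DOPA,C9H11NO4,tyrosine
dopamine,C8H11NO2,tyrosine
4-hydroxyphenyllactate,C9H10O4,tyrosine
4-hydroxyphenylacetate,C8H8O3,tyrosine
norcoclaurine,C16H17NO3,benzylisoquinoline
coclaurine,C17H19NO3,benzylisoquinoline
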