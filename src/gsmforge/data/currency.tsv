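compound_id
C00001
C00002
C00003
C00004
C00005
C00006
C00007
C00008
C00009
C00011
C00080
C05359
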