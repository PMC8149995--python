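alias_id	canonical_id
C00031	C00267
C00221	C00267
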