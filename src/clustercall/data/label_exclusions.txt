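# Ambiguous reference labels dropped from benchmarking
pp
mhc class ii
psc
co-expression
immune other
unclassified
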