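cinv-audit rule tables v1 (JSCO 2015; ASCO 2020; NCCN 2.2020; MASCC/ESMO 2016)
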