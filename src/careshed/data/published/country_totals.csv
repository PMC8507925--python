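country,total
Ireland,4761865
Spain,46722980
Switzerland,8484130
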