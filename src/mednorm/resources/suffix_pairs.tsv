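ive	ion
ic	ia
ic	y
us	ness
al	um
osis	otic
emia	emic
itis	itic
oma	omatous
pathy	pathic
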