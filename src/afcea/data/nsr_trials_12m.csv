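label,n,events
Forleo 2009,35,15
Jais 2008,55,13
Pappone 2006,99,22
Krittayaphong 2003,15,6
Wilber 2010,61,10
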