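version,mdc95,mcid_020,mcid_033,mcid_050
8item,1.25,0.25,0.41,0.63
10item,1.03,0.22,0.37,0.56
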