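residue,resname,lnP
8,LEU,8.1
9,VAL,9.9
13,VAL,7.2
16,ALA,7.1
17,LYS,6.6
18,LYS,8.2
22,GLN,9.5
27,ALA,6.7
28,GLN,8.2
52,ASP,8.5
56,ASN,8.4
58,ALA,9
59,GLN,10.5
63,VAL,7.4
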