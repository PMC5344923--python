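residue,resname,lnP
9,ASP,8
10,TYR,9.2
11,THR,10.2
16,VAL,11.5
17,GLN,11.6
18,LEU,11.2
21,GLU,8.5
23,GLU,6
37,LEU,6.1
38,LEU,7.5
41,PHE,6
42,VAL,10.3
53,LEU,3.5
54,ILE,3.6
55,TYR,4.4
56,TYR,5.6
67,GLY,8.1
69,VAL,8.8
72,ILE,9
73,LYS,9.5
74,GLU,9
75,TRP,8.8
76,ARG,9.9
77,ALA,9.8
78,ALA,8
85,LYS,6.8
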