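case,sample,cellularity,necrosis_class,vessels,habitats
2,A,1,0,0,"7,8"
2,B,4,0,43,"2"
2,C,4,1,21,"5"
5,A,3,2,1,"6"
5,B,4,4,1,"2,5"
5,C,3,5,3,"5,7,8"
5,D,3,3,6,"5,6"
8,A,2,0,0,"1"
8,B,2,0,0,"1"
8,C,2,0,1,"1"
8,D,2,0,0,"1"
9,A,5,2,20,"1"
9,B,5,2,19,"1"
10,A,1,0,0,"7,8"
10,B,3,1,8,"2"
12,A,1,0,4,"8,2,6"
12,B,3,2,4,"2,6"
12,C,4,1,8,"2"
13,A,1,0,0,"7"
13,B,1,0,0,"5"
13,C,3,0,0,"3"
13,D,3,0,2,"1,3"
14,A,3,0,5,"7,8,6"
14,B,4,0,11,"6"
16,A,1,0,0,"7,8"
16,B,3,0,28,"1"
16,C,5,1,11,"2"
16,D,,5,,"5,7"
17,A,4,0,6,"2"
17,B,4,1,7,"2"
17,C,4,0,4,"6,2"
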