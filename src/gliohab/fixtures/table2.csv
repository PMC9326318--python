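habitat,vp_level,faza_level,md_level,p1,p2,p3,p4,p5,p6,p7,p8,p9,p10,p11,p12,p13,p14,p15,p16,p17
1,High,High,High,0.2,11.1,2.0,1.3,8.0,6.7,4.8,1.9,2.6,1.7,5.4,1.9,4.4,6.7,11.1,6.4,0.7
2,High,High,Low,25.1,10.2,13.6,9.1,7.4,11.6,16.0,3.1,2.1,23.6,3.1,16.2,11.7,6.8,6.7,25.8,14.5
3,High,Low,High,2.0,4.8,3.5,16.8,1.4,1.1,1.4,10.6,9.5,2.1,3.3,2.6,6.6,5.2,1.7,2.4,1.3
4,High,Low,Low,5.0,12.9,2.2,4.9,1.5,1.4,2.6,9.4,12.0,5.1,6.0,3.1,7.1,4.3,2.3,7.2,1.6
5,Low,High,High,0.3,5.7,1.9,1.2,10.4,3.7,6.2,0.6,0.9,2.1,4.3,0.4,8.5,12.4,7.1,5.6,0.3
6,Low,High,Low,6.3,3.7,4.1,2.8,23.0,4.6,8.1,0.7,1.0,7.7,3.4,5.9,11.8,18.6,2.2,7.0,9.3
7,Low,Low,High,45.3,7.0,54.8,34.3,21.2,37.0,31.4,41.5,28.9,15.4,12.8,35.1,33.9,21.1,37.7,18.0,43.2
8,Low,Low,Low,15.7,44.7,17.8,29.6,27.2,33.8,29.3,32.1,43.1,42.2,61.7,34.7,15.9,24.7,31.2,27.7,29.1
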