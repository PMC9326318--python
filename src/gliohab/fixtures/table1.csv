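patient,age_years,sex,ce_volume_cm3,flair_volume_cm3,n_lesions,procedure,histology,who_grade,p53,atrx,gfap,ki67,mgmt,idh1,os_weeks
1,71,F,23.4,67.8,1,Resection,GBL,IV,20%,+,+,10%,methylated,wild-type,40
2,58,M,4.4,10.2,1,Biopsy,GBL,IV,15%,+,+,20%,unknown,mutated,76
3,56,M,25.0,111.6,1,Resection,GBL,IV,5%,+,+,25%,methylated,wild-type,214
4,61,M,1.1,10.9,1,Resection,AA,III,5%,-,+,30%,methylated,wild-type,71
5,73,F,61.4,130.2,1,Biopsy,GBL,IV,5-10%,+,+,7%,unknown,wild-type,21
6,77,M,56.1,184.0,1,Resection,GBL,IV,0,+,+,15%,methylated,wild-type,16
7,79,M,79.1,185.4,1,Resection,GBL,IV,10%,-,+,20%,methylated,wild-type,26
8,69,F,1.6,50.1,5,Biopsy,AA,III,5%,+,+,3%,unknown,wild-type,13
9,64,M,2.6,91.1,3,Biopsy,GBL,IV,10%,+,+,35%,unknown,wild-type,21
10,81,M,34.4,98.1,4,Biopsy,AO,III,0,+,++,15%,unknown,mutated,10
11,65,M,30.3,136.5,1,Resection,GBL,IV,0,+,+,15%,methylated,wild-type,44
12,77,M,5.4,23.4,1,Biopsy,GBL,IV,,+,,5%,unknown,wild-type,13
13,41,M,0.0,146.5,1,Biopsy,AA,III,3%,+,+,10%,methylated,mutated,10
14,64,M,53.0,70.8,1,Biopsy,AA,III,<1%,+,-,20%,unmethylated,wild-type,8
15,61,M,26.8,102.9,1,Resection,GBL,IV,40%,+,+,40%,unknown,wild-type,88
16,57,F,8.0,18.8,1,Biopsy,GBL,IV,<5%,+,+,5%,unknown,wild-type,222
17,44,F,16.8,162.3,1,Biopsy,GBL,IV,70%,-,+,25%,unknown,wild-type,9
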