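patient_id,age,sex,cancer_site,prior_lines,drug,regimen,pfs_months
203,67,F,GI/NE,1,everolimus,everolimus,60.0+
148,82,M,GI/NE,2,everolimus,everolimus,11.6
6,64,F,UP,1,everolimus,everolimus,8.1
117,34,M,HN,2,everolimus,everolimus,1.9
227,56,M,LS,4,everolimus,everolimus,1.7
90,74,M,HN,2,everolimus,everolimus,1.3
83,59,M,HN,4,axitinib,axitinib,8.8
223,65,F,HN,3,axitinib,axitinib,7.1
259,53,F,HN,4,axitinib,axitinib,6.2
25,65,M,HN,2,axitinib,axitinib,5.3
88,56,M,Lung,1,axitinib,axitinib,2.9
149,54,F,CRC,5,trametinib,trametinib,7.4
100,43,M,Lung,2,trametinib,trametinib,6.6
118,78,F,Lung,3,trametinib,trametinib,3.1
156,71,F,Lung,2,afatinib,afatinib+cetuximab,14.3
235,60,F,Lung,1,afatinib,afatinib,11.3
136,79,M,Lung,3,afatinib,afatinib,0.4
237,47,M,HN,6,fgfr,BGJ398,19.3
247,67,M,Esophagus,2,fgfr,TAS-120,1.6
228,38,M,CRC,5,fgfr,TAS-120,0.7
183,66,M,CRC,2,anti-pd1,pembrolizumab,61.0+
294,57,M,HN,1,anti-pd1,nivolumab,1.7
270,76,F,CRC,3,anti-pd1,atezolizumab,0.9
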