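study_id,author_year,country,ethnicity,genotyping_method,variant,n_case,n_control,case_AA,case_AB,case_BB,ctrl_AA,ctrl_AB,ctrl_BB,reported_maf,reported_hwe_p,nos
vijayakrishnan2010_asian,Vijayakrishnan 2010,UK,Asian,KASP,rs3731217,190,182,148,40,2,138,43,1,0.124,0.222,7
pastorczak2011,Pastorczak 2011,Poland,Caucasian,KASP,rs3731217,387,715,304,76,7,551,148,16,0.126,0.112,9
orsi2012,Orsi 2012,France,Caucasian,Illumina array,rs3731217,441,1984,338,96,7,1452,486,46,0.146,0.481,10
burmeister2014,Burmeister 2014,Germany,Caucasian,TaqMan,rs3731217,322,1503,260,60,2,1092,379,32,0.147,0.895,8
vijayakrishnan2015_a,Vijayakrishnan 2015,UK,Caucasian,Illumina array,rs3731217,824,5200,659,149,16,3778,1311,111,0.147,0.826,9
vijayakrishnan2015_b,Vijayakrishnan 2015,UK,Caucasian,Illumina array,rs3731217,834,2024,685,140,9,1523,468,33,0.132,0.666,9
hungate2016_caucasian,Hungate 2016,USA,Caucasian,ABI,rs3731217,1406,1384,1166,224,16,1052,313,19,0.127,0.429,9
hungate2016_african,Hungate 2016,USA,African,ABI,rs3731217,203,1243,172,31,0,1044,187,12,0.085,0.266,9
hungate2016_hispanic,Hungate 2016,USA,Hispanic,ABI,rs3731217,391,978,344,46,1,810,157,11,0.092,0.279,9
kreile2016,Kreile 2016,Latvia,Caucasian,PCR-RFLP,rs3731217,76,121,64,12,0,95,26,0,0.107,,8
gharbi2016,Gharbi 2016,Tunis,African,PCR,rs3731217,58,150,13,31,14,21,78,51,0.600,0.307,9
alabsi2017,Al-Absi 2017,Yemen,Asian,Dynamic Array,rs3731217,136,153,104,29,3,111,36,6,0.157,0.171,9
bardsiri2022_rs3731217,Bardsiri 2022,Iran,Asian,HRM,rs3731217,50,50,48,2,0,49,1,0,0.010,0.943,7
alzaya2023,Al-Zaya 2023,Gaza,Asian,AS-PCR,rs3731217,78,100,12,62,4,24,45,31,0.535,0.339,7
healy2007,Healy 2007,Canada,Caucasian,PCR,rs3731249,227,275,195,30,2,256,18,1,0.036,0.273,9
vijayakrishnan2010_a,Vijayakrishnan 2010,UK,Caucasian,Illumina array,rs3731249,835,2024,722,101,12,1916,106,2,0.027,0.670,9
vijayakrishnan2010_b,Vijayakrishnan 2010,UK,Caucasian,Illumina array,rs3731249,823,5198,750,69,4,4933,261,4,0.026,0.774,9
vijayakrishnan2010_c,Vijayakrishnan 2010,UK,Caucasian,KASP,rs3731249,519,1016,472,45,2,974,41,1,0.021,0.409,9
xu2015_a,Xu 2015,USA,Caucasian,Illumina array,rs3731249,1773,10241,1541,224,8,9615,619,7,0.031,0.358,8
xu2015_b,Xu 2015,USA,Caucasian,Illumina array,rs3731249,409,1599,357,45,7,1467,130,2,0.042,0.615,8
gutierrezcamino2017,Gutierrez-Camino 2017,Spain,Caucasian,PCR,rs3731249,171,234,142,28,1,217,16,1,0.038,0.247,9
bardsiri2022_rs3731249,Bardsiri 2022,Iran,Asian,HRM,rs3731249,50,50,41,8,1,49,1,0,0.010,0.943,7
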