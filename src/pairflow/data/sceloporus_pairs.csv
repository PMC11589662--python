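comparison,clade_a,clade_b,taxon_a,taxon_b,n_individuals,n_snps,clade_admixture_mean_freq,clade_admixture_prop_ind,pop_admixture_mean_freq,pop_admixture_prop_ind,morphology_pc,climate_pc,time_myr,distance_km
1,1,9,S. minor,S. ornatus,7,6251,0.00,0.00,0.00,0.00,14.7,79.2,4.14,173.1
2,1,10,S. minor,S. ornatus,24,15059,0.31,0.08,0.00,0.00,14.7,39.2,4.14,113.6
3,1,12,S. minor,S. oberon,38,15312,0.75,0.16,2.85,0.60,5.7,20.4,4.14,116.0
4,1,11,S. minor,S. oberon,21,13204,0.33,0.10,0.10,0.11,8.0,9.2,4.14,135.1
5,1,2,S. minor,S. minor,18,14580,0.00,0.00,0.00,0.00,1.8,5.7,3.73,168.1
6,1,3,S. minor,S. minor,10,10012,0.00,0.00,0.00,0.00,2.6,20.0,3.94,259.6
7,2,3,S. minor,S. minor,18,15587,6.55,0.39,11.21,0.22,2.9,14.3,3.94,191.9
8,2,11,S. minor,S. oberon,29,18811,1.24,0.21,2.65,0.33,8.2,12.7,4.14,118.4
9,2,6,S. minor,Sceloporus sp. N,18,15065,0.69,0.11,0.00,0.00,10.3,53.6,4.14,96.1
10,2,7,S. minor,Sceloporus sp. S,19,15200,0.59,0.11,0.54,0.11,4.6,89.6,4.14,145.8
11,3,4,S. minor,S. minor,15,15283,0.23,0.07,0.57,0.06,4.6,42.7,3.73,238.1
12,3,7,S. minor,Sceloporus sp. S,11,10794,0.26,0.09,0.29,0.10,3.6,104.0,4.14,172.1
13,4,7,S. minor,Sceloporus sp. S,16,14912,1.39,0.19,0.71,0.13,3.8,61.7,4.14,182.0
14,5,12,S. cyanogenys,S. oberon,36,14565,4.76,0.28,7.16,0.80,5.7,40.9,3.87,156.9
15,5,10,S. cyanogenys,S. ornatus,22,14553,0.66,0.09,2.92,0.20,15.0,93.3,3.87,176.5
16,6,7,Sceloporus sp. N,Sceloporus sp. S,11,9051,0.73,0.09,0.73,0.09,8.1,39.1,3.32,131.4
17,8,9,S. cyanostictus,S. ornatus,6,5797,0.00,0.00,0.00,0.00,7.6,21.7,3.40,84.2
18,8,10,S. cyanostictus,S. ornatus,23,14891,0.81,0.13,0.20,0.33,7.6,18.3,3.40,140.2
19,9,10,S. ornatus,S. ornatus,21,12614,13.33,0.14,87.32,1.00,0,40,2.67,162.3
20,10,12,S. ornatus,S. oberon,52,20556,1.10,0.25,0.90,0.14,12.4,59.6,3.70,79.2
21,11,12,S. oberon,S. oberon,49,17318,7.00,0.45,42.63,1.00,4.9,11.7,3.30,61.2
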