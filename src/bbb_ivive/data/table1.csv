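casrn,compound,papp_ab_1e6,sd_ab_1e6,ab_bound,papp_ba_1e6,sd_ba_1e6,ba_bound,er_printed,rate_printed
22083-74-5,DL-Nicotine,0.08,0.01,exact,0.08,0.04,exact,0.98,Slow
89-25-8,Edaravone,0.41,0.13,exact,0.25,0.16,exact,0.61,Slow
52-53-9,Verapamil,0.57,0.02,exact,1.0,0.14,exact,1.75,Slow
88-99-3,Phthalic acid,0.75,0.19,exact,0.59,0.05,exact,0.79,Slow
1222998-36-8,Torin 1,2.2,0.07,exact,1.3,0.6,exact,0.56,Moderate
103-90-2,Acetaminophen,3.7,0.64,exact,2.3,0.5,exact,0.62,Moderate
19216-56-9,Prazosin,3.7,0.8,exact,7.0,1.8,exact,1.88,Moderate
53230-10-7,Mefloquine,4.7,0.1,exact,36.9,4.4,exact,7.81,Moderate
50-23-7,Hydrocortisone,4.8,2.5,exact,1.3,0.6,exact,0.26,Moderate
259793-96-9,Favipiravir,5.2,2.4,exact,4.4,1.7,exact,0.83,Moderate
535-80-8,3-Chlorobenzoic acid,5.6,0.6,exact,3.1,0.6,exact,0.55,Moderate
123-31-9,Hydroquinone,7.2,3.5,exact,10.0,3.9,exact,1.38,Moderate
84-66-2,Diethyl phthalate,7.7,1.1,exact,7.2,1.6,exact,0.94,Moderate
88321-09-9,Aloxistatin,8.1,0.8,exact,6.6,0.4,exact,0.81,Moderate
2628280-40-8,Nirmatrelvir,8.5,0.1,exact,6.9,0.2,exact,0.81,Moderate
551-16-6,6-Aminopenicillic acid,10.6,1.6,exact,16.3,1.9,exact,1.54,Moderate
298-46-4,Carbamazepine,12.2,1.3,exact,10.9,0.4,exact,0.90,Fast
60-92-4,"Adenosine 3',5'-cyclic monophosphate (cAMP)",12.4,2.8,exact,13.0,2.8,exact,1.04,Fast
15686-71-2,Cephalexin,12.7,3.3,exact,25.8,2.5,exact,2.03,Fast
5786-21-0,Clozapine,13.4,1.2,exact,12.0,1.5,exact,0.89,Fast
579-75-9,2-Methoxybenzoic acid,13.4,1.5,exact,10.5,0.6,exact,0.78,Fast
2492423-29-5,Molnupiravir,13.4,0.1,exact,10.7,0.9,exact,0.80,Fast
51-28-5,"2,4-Dinitrophenol",13.5,0.7,exact,11.3,1.5,exact,0.84,Fast
2798-05-2,"4,4'-Methylenebis(phenyl isothiocyanate)",13.5,3.9,exact,9.8,3.1,exact,0.73,Fast
120-83-2,"2,4-Dichlorophenol",13.6,2.2,exact,13.5,3.0,exact,0.99,Fast
54910-89-3,Fluoxetine,14.4,4.7,exact,20.1,3.6,exact,1.4,Fast
57-41-0,Phenytoin,15.1,2.8,exact,14.6,2.2,exact,0.96,Fast
118-92-3,Anthranilic acid,15.9,1.6,exact,12.2,0.77,exact,0.77,Fast
58-08-2,Caffeine,16.6,1.7,exact,10.6,2.3,exact,0.64,Fast
na,BisMetPtNH2,17.4,1.5,exact,22.9,3.5,exact,1.31,Fast
67-20-9,Nitrofurantoin,18.3,0.6,exact,23.5,1.3,exact,1.28,Fast
414864-00-9,Belinostat,18.8,3.6,exact,0.07,0.01,exact,0.004,Fast
4044-65-9,"1,4-Phenylene diisothiocyanate",20.0,3.0,exact,6.6,1.8,exact,0.33,Fast
105650-23-5,"2-Amino-1-methyl-6-phenylimidazo[4,5-b]pyridine",20.7,6.0,exact,14.6,3.0,exact,0.70,Fast
54-64-8,Thimerosal,20.8,2.2,exact,19.4,1.6,exact,0.93,Fast
4685-14-7,Paraquat,21.9,3.7,exact,20.6,7.0,exact,0.94,Fast
80-05-7,Bisphenol A,22.9,6.7,exact,28.5,1.8,exact,1.24,Fast
101-26-8,Pyridostigmine Bromide,23.0,3.4,exact,14.0,7.6,exact,0.61,Fast
987-78-0,Cytidine 5'-diphosphocholine,25.9,3.0,exact,37.5,0.7,exact,1.45,Fast
118-91-2,2-Chlorobenzoic acid,28.7,5.5,exact,26.6,3.8,exact,0.93,Fast
2474-72-8,Hydroxyquinone,29.9,3.4,exact,9.3,0.5,exact,0.31,Fast
636-00-0,6-Hydroxydopamine hydrobromide,31.3,3.9,exact,10.8,1.9,exact,0.34,Fast
na,BisMetPt,33.9,4.0,exact,36.0,2.6,exact,1.06,Fast
6998-60-3,Rifamycin SV,45.9,2.1,exact,29.9,7.6,exact,0.65,Fast
150-76-5,Methoxyphenol,54.8,11.1,exact,37.6,10.2,exact,0.69,Fast
10265-92-6,Methanidophos,56.1,7.7,exact,18.3,11.9,exact,0.33,Fast
99-66-1,Valproic acid,500,,lower,117,14,exact,< 0.24,Very fast
43121-43-3,Triadimefon,500,,lower,149,14,exact,< 0.30,Very fast
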