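taxon,specimen,AMaSCD,AMiSCD,PMaSCD,PMiSCD,HMaSCD,HMiSCD,log10_bm_grams,bm_estimated
Atelerix,unvouchered,1.33,1.22,1.23,1.08,0.96,0.89,2.52,False
Canis,TMMM-150,1.73,1.72,1.42,1.42,1.50,1.46,4.60,False
Cavia,TMM-M-7283,2.15,1.53,1.46,1.44,1.90,1.16,2.86,False
Chrysochloris,AMNH82372,1.20,0.78,0.68,0.48,0.67,0.58,1.67,False
Cynocephalus,AMNH187859,2.09,1.95,1.64,1.53,1.49,1.37,3.10,False
Dasypus,TMM-M-152,1.90,1.50,1.63,1.62,1.45,1.38,3.60,False
Dasypus,TMM-M-1065,1.96,1.66,1.80,1.72,1.44,1.40,3.60,False
Dasypus,TMM-M-1880,2.06,1.31,1.88,1.72,1.58,1.54,3.60,False
Dasypus,TMM-M-1885,2.15,1.31,1.94,1.93,1.48,1.37,3.60,False
Didelphis,TMM-M-2517,1.47,1.40,1.11,1.10,0.92,0.84,3.39,False
Equus,TMM-M-171,3.53,3.43,3.49,3.20,3.10,3.04,5.61,False
Eumetopias,unvouchered,3.32,2.38,2.83,2.32,2.59,1.91,5.58,False
Felis,TMM-M-968,1.99,1.67,1.84,1.73,1.73,1.53,3.46,False
Hemicentetes,AMNH161535,1.13,0.95,0.79,0.65,0.69,0.58,2.13,False
Homo,UTO-HS01,1.99,1.83,2.83,2.38,2.72,2.51,4.77,False
Macaca,TMM-M-5987,2.68,1.34,2.36,2.27,2.36,2.02,5.67,False
Macroscelides,AMNH161535,1.19,1.16,1.07,0.73,1.17,0.76,1.59,False
Manis,AMNH53896,1.40,1.13,1.40,1.15,0.82,0.78,3.19,False
Monodelphis,TMM-M-7599,1.02,1.00,0.94,0.87,0.74,0.69,1.97,False
Mus,TMM-M-3196,0.86,0.58,0.71,0.47,0.59,0.52,1.29,False
Nycteris,AMNH268369,0.99,0.85,0.81,0.70,0.96,0.61,1.47,False
Orycteropus,AMNH51909,3.36,2.86,4.07,2.95,3.44,2.88,4.75,False
Procavia,TMM-M-4351,2.15,1.57,2.30,1.72,2.03,1.48,3.47,False
Pteropus,AMNH237593,1.54,1.36,1.45,1.15,1.28,1.25,2.50,False
Rhinolophus,AMNH245591,0.87,0.70,0.74,0.66,0.92,0.77,1.35,False
Sorex,unvouchered,0.78,0.41,0.70,0.43,0.44,0.44,0.84,False
Sus,TMM-M-2689,2.46,2.00,2.20,1.53,1.88,1.56,4.93,False
Sylvilagus,TMM-M-2689,1.75,1.69,1.42,1.28,1.27,1.18,3.08,False
Tadarida,TMM-M-3030,0.83,0.73,0.69,0.61,0.89,0.61,1.10,False
Trichechus,MSW03156,4.07,4.06,3.72,3.59,4.53,4.27,5.67,False
Tupaia,TMM-M-2256,1.91,1.61,1.67,1.26,1.84,1.20,2.12,False
Tursiops,SDNHM21212,1.08,0.96,0.80,0.68,1.29,1.27,5.45,False
Endothiodon,MTA-ACL-002,5.24,2.00,4.61,1.81,3.24,1.74,5.15,True
Endothiodon,MTA-ACL-003,4.93,2.74,3.91,1.87,2.97,1.62,5.06,True
Endothiodon,MTA-ACL-001,5.15,2.64,4.24,1.96,3.47,2.09,5.26,True
Niassodon,ML1620,2.4,1.68,2.08,1.08,3.46,2.93,2.69,True
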