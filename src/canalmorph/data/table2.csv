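specimen,variable,rep1,rep2,rep3,rep4,rep5
MTA-ACL-001,LDASC,0.75,0.80,0.80,0.84,0.76
MTA-ACL-001,LDPSC,0.42,0.35,0.40,0.42,0.39
MTA-ACL-001,LDHSC,0.57,0.58,1.02,0.88,0.66
MTA-ACL-002,LDASC,0.69,0.81,0.94,0.59,0.53
MTA-ACL-002,LDPSC,0.43,0.38,0.44,0.44,0.42
MTA-ACL-002,LDHSC,0.76,0.77,0.73,0.88,0.66
MTA-ACL-003,LDASC,0.61,0.68,0.64,0.70,0.71
MTA-ACL-003,LDPSC,0.41,0.36,0.40,0.42,0.41
MTA-ACL-003,LDHSC,0.41,0.62,0.47,0.77,0.51
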