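specimen,variable,rep1,rep2,rep3,rep4,rep5
MTA-ACL-001,AAHSC,91.7,92,90.6,91.5,89.6
MTA-ACL-001,APHSC,90.4,90.5,90.1,89.2,90.1
MTA-ACL-001,AAPSC,89.7,89.4,88.8,89.6,90.9
MTA-ACL-002,AAHSC,91.2,92.2,92.2,92.5,92.1
MTA-ACL-002,APHSC,91.7,91.2,92.0,89.2,89.8
MTA-ACL-002,AAPSC,88.6,90.1,89,89.0,89.7
MTA-ACL-003,AAHSC,90.5,91.4,91.5,90.7,88.9
MTA-ACL-003,APHSC,89.5,90.4,90.2,90.4,89.6
MTA-ACL-003,AAPSC,87,88,90.3,90.4,89.6
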