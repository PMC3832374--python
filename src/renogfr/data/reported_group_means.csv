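group,method,mean,sd
SD,optical,4.34,2.22
SD,mri,2.10,0.64
UNX,optical,2.34,0.90
UNX,mri,1.17,0.38
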