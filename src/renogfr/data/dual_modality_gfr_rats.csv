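animal_id,group,gfr_optical,gfr_mri
SD1,SD,7.23,2.22
SD2,SD,4.67,2.25
SD3,SD,5.48,2.63
SD4,SD,2.58,2.48
SD5,SD,1.72,1.32
SD6,SD,3.24,1.52
UNX1,UNX,2.30,0.59
UNX2,UNX,2.78,1.33
UNX3,UNX,1.16,0.84
UNX4,UNX,1.40,1.21
UNX5,UNX,3.11,1.55
UNX6,UNX,3.32,1.50
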