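compound_id,target_id,binding_energy
CH-1,CARM1,-12.41
CH-1,HDAC2,-12.37
CH-2,CARM1,-12.29
CH-2,HDAC2,-12.12
CH-3,CARM1,-12.07
CH-3,HDAC2,-12.25
CH-4,CARM1,-11.68
CH-4,HDAC2,-12.09
CH-5,CARM1,-11.54
CH-5,HDAC2,-11.86
CH-6,CARM1,-11.49
CH-6,HDAC2,-11.94
CH-7,CARM1,-11.32
CH-7,HDAC2,-11.71
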