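id,product_line,incomplete,VT1,VT2,VT3,VT4,VT5,VT6,VT7,VP1,VP2,VP3
dairy-001,alimentos,0,4,3,3,2,3,2,5,5,4,3
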