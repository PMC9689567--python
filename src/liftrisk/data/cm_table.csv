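coupling,v_lt75,v_ge75
good,1.00,1.00
fair,0.95,1.00
poor,0.90,0.90
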