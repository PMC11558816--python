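background,blk_nhej_pct,cd_nhej_pct
AgNDO,22.5,100.0
AgZAN,18.6,94.0
AgKIS,5.0,100.0
AcMOP,31.7,100.0
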