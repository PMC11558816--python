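background,lineage,eye,cfp,count,printed_pct,printed_denominator
AgKIS,male_drive_parent,black,pos,1718,99.6,1725
AgKIS,male_drive_parent,small_tear,pos,7,0.4,1725
AgNDO,male_drive_parent,black,pos,5777,99.9,5780
AgNDO,male_drive_parent,small_tear,pos,3,0.1,5780
AgZAN,male_drive_parent,black,pos,2795,99.3,2814
AgZAN,male_drive_parent,small_tear,pos,19,0.7,2814
AcMOP,male_drive_parent,black,pos,1632,99.6,1639
AcMOP,male_drive_parent,small_tear,pos,7,0.4,1639
AaDON,male_drive_parent,black,pos,4145,99.98,4146
AaDON,male_drive_parent,small_tear,pos,1,0.02,4146
AgKIS,female_drive_parent,black,pos,1126,22.3,5040
AgKIS,female_drive_parent,small_tear,pos,1393,27.7,5040
AgKIS,female_drive_parent,big_tear,pos,2127,42.2,5040
AgKIS,female_drive_parent,cardinal,pos,394,7.8,5040
AgNDO,female_drive_parent,black,pos,1538,27.0,5691
AgNDO,female_drive_parent,small_tear,pos,1884,33.1,5691
AgNDO,female_drive_parent,big_tear,pos,1816,31.9,5691
AgNDO,female_drive_parent,cardinal,pos,453,8.0,5961
AgZAN,female_drive_parent,black,pos,1403,32.7,4292
AgZAN,female_drive_parent,small_tear,pos,1448,33.7,4292
AgZAN,female_drive_parent,big_tear,pos,1132,26.4,4292
AgZAN,female_drive_parent,cardinal,pos,309,7.2,4292
AcMOP,female_drive_parent,black,pos,618,21.6,2858
AcMOP,female_drive_parent,small_tear,pos,619,21.7,2858
AcMOP,female_drive_parent,big_tear,pos,1288,45.0,2858
AcMOP,female_drive_parent,cardinal,pos,333,11.7,2858
AaDON,female_drive_parent,black,pos,1083,33.7,3209
AaDON,female_drive_parent,small_tear,pos,958,29.9,3209
AaDON,female_drive_parent,big_tear,pos,916,28.5,3209
AaDON,female_drive_parent,cardinal,pos,252,7.9,3209
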