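background,lineage,eye,cfp,count,printed_pct,printed_denominator
AgKIS,male_drive_parent,black,pos,189,3.7,5036
AgKIS,male_drive_parent,cardinal,pos,4843,96.2,5036
AgKIS,male_drive_parent,small_tear,pos,4,0.1,5036
AgNDO,male_drive_parent,black,pos,263,6.5,4023
AgNDO,male_drive_parent,cardinal,pos,3759,93.4,4023
AgNDO,male_drive_parent,small_tear,pos,1,0.1,4023
AgZAN,male_drive_parent,black,pos,67,1.5,4409
AgZAN,male_drive_parent,cardinal,pos,4345,98.5,4409
AcMOP,male_drive_parent,black,pos,11,0.3,3795
AcMOP,male_drive_parent,cardinal,pos,3784,99.7,3795
AgKIS,female_drive_parent,black,pos,540,11.8,4567
AgKIS,female_drive_parent,cardinal,pos,3999,87.6,4567
AgKIS,female_drive_parent,black,neg,25,0.5,4567
AgKIS,female_drive_parent,cardinal,neg,3,0.1,4567
AgNDO,female_drive_parent,black,pos,484,8.3,5835
AgNDO,female_drive_parent,cardinal,pos,5278,90.5,5835
AgNDO,female_drive_parent,small_tear,pos,2,0.03,5835
AgNDO,female_drive_parent,black,neg,57,1.0,5835
AgNDO,female_drive_parent,cardinal,neg,14,0.2,5835
AgZAN,female_drive_parent,black,pos,295,8.3,3570
AgZAN,female_drive_parent,cardinal,pos,3243,90.8,3570
AgZAN,female_drive_parent,small_tear,pos,4,0.1,3570
AgZAN,female_drive_parent,black,neg,7,0.2,3570
AgZAN,female_drive_parent,cardinal,neg,21,0.6,3570
AcMOP,female_drive_parent,black,pos,307,6.2,4962
AcMOP,female_drive_parent,cardinal,pos,4614,93.0,4962
AcMOP,female_drive_parent,black,neg,16,0.3,4962
AcMOP,female_drive_parent,cardinal,neg,25,0.5,4962
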