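taxon,Pueblo,Moran,Putnam,Admiral,Belle Plains,Clyde,Lueders,Arroyo,Vale,Choza,San Angelo
sp_Pueblo_00,1,0,0,0,0,0,0,0,0,0,0
sp_Pueblo_01,2,0,0,0,0,0,0,0,0,0,0
sp_Pueblo_02,1,0,0,0,0,0,0,0,0,0,0
sp_Pueblo_03,6,0,0,0,0,0,0,0,0,0,0
sp_Pueblo_04,3,0,0,0,0,0,0,0,0,0,0
sp_Pueblo_05,3,0,0,0,0,0,0,0,0,0,0
sp_Moran_00,0,1,0,0,0,0,0,0,0,0,0
sp_Moran_01,0,1,0,0,0,0,0,0,0,0,0
sp_Moran_02,0,11,0,0,0,0,0,0,0,0,0
sp_Moran_03,0,12,0,0,0,0,0,0,0,0,0
sp_Moran_04,0,3,0,0,0,0,0,0,0,0,0
sp_Putnam_00,0,0,8,0,0,0,0,0,0,0,0
sp_Putnam_01,0,0,1,0,0,0,0,0,0,0,0
sp_Putnam_02,0,0,2,0,0,0,0,0,0,0,0
sp_Putnam_03,0,0,3,0,0,0,0,0,0,0,0
sp_Admiral_00,0,0,0,1,0,0,0,0,0,0,0
sp_Admiral_01,0,0,0,1,0,0,0,0,0,0,0
sp_Admiral_02,0,0,0,4,0,0,0,0,0,0,0
sp_Admiral_03,0,0,0,1,0,0,0,0,0,0,0
sp_Admiral_04,0,0,0,2,0,0,0,0,0,0,0
sp_Belle_Plains_00,0,0,0,0,5,0,0,0,0,0,0
sp_Belle_Plains_01,0,0,0,0,2,0,0,0,0,0,0
sp_Belle_Plains_02,0,0,0,0,2,0,0,0,0,0,0
sp_Belle_Plains_03,0,0,0,0,3,0,0,0,0,0,0
sp_Belle_Plains_04,0,0,0,0,3,0,0,0,0,0,0
sp_Clyde_00,0,0,0,0,0,2,0,0,0,0,0
sp_Clyde_01,0,0,0,0,0,11,0,0,0,0,0
sp_Clyde_02,0,0,0,0,0,1,0,0,0,0,0
sp_Clyde_03,0,0,0,0,0,9,0,0,0,0,0
sp_Lueders_00,0,0,0,0,0,0,3,0,0,0,0
sp_Lueders_01,0,0,0,0,0,0,5,0,0,0,0
sp_Lueders_02,0,0,0,0,0,0,2,0,0,0,0
sp_Lueders_03,0,0,0,0,0,0,7,0,0,0,0
sp_Lueders_04,0,0,0,0,0,0,1,0,0,0,0
sp_Arroyo_00,0,0,0,0,0,0,0,3,0,0,0
sp_Arroyo_01,0,0,0,0,0,0,0,3,0,0,0
sp_Arroyo_02,0,0,0,0,0,0,0,7,0,0,0
sp_Arroyo_03,0,0,0,0,0,0,0,19,0,0,0
sp_Arroyo_04,0,0,0,0,0,0,0,5,0,0,0
sp_Arroyo_05,0,0,0,0,0,0,0,9,0,0,0
sp_Arroyo_06,0,0,0,0,0,0,0,2,0,0,0
sp_Arroyo_07,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_08,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_09,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_10,0,0,0,0,0,0,0,2,0,0,0
sp_Arroyo_11,0,0,0,0,0,0,0,2,0,0,0
sp_Arroyo_12,0,0,0,0,0,0,0,3,0,0,0
sp_Arroyo_13,0,0,0,0,0,0,0,14,0,0,0
sp_Arroyo_14,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_15,0,0,0,0,0,0,0,2,0,0,0
sp_Arroyo_16,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_17,0,0,0,0,0,0,0,1,0,0,0
sp_Arroyo_18,0,0,0,0,0,0,0,2,0,0,0
sp_Arroyo_19,0,0,0,0,0,0,0,7,0,0,0
sp_Arroyo_20,0,0,0,0,0,0,0,7,0,0,0
sp_Arroyo_21,0,0,0,0,0,0,0,2,0,0,0
sp_Vale_00,0,0,0,0,0,0,0,0,3,0,0
sp_Vale_01,0,0,0,0,0,0,0,0,1,0,0
sp_Vale_02,0,0,0,0,0,0,0,0,3,0,0
sp_Vale_03,0,0,0,0,0,0,0,0,1,0,0
sp_Vale_04,0,0,0,0,0,0,0,0,4,0,0
sp_Vale_05,0,0,0,0,0,0,0,0,2,0,0
sp_Vale_06,0,0,0,0,0,0,0,0,4,0,0
sp_Vale_07,0,0,0,0,0,0,0,0,1,0,0
sp_Choza_00,0,0,0,0,0,0,0,0,0,1,0
sp_Choza_01,0,0,0,0,0,0,0,0,0,1,0
sp_San_Angelo_00,0,0,0,0,0,0,0,0,0,0,1
sp_San_Angelo_01,0,0,0,0,0,0,0,0,0,0,12
sp_San_Angelo_02,0,0,0,0,0,0,0,0,0,0,3
sp_San_Angelo_03,0,0,0,0,0,0,0,0,0,0,3
sp_San_Angelo_04,0,0,0,0,0,0,0,0,0,0,4
sp_San_Angelo_05,0,0,0,0,0,0,0,0,0,0,2
sp_San_Angelo_06,0,0,0,0,0,0,0,0,0,0,2
sp_San_Angelo_07,0,0,0,0,0,0,0,0,0,0,4
sp_shared_00,2,1,0,0,0,0,0,0,0,0,0
sp_shared_01,5,6,0,0,0,0,0,0,0,0,0
sp_shared_02,3,1,0,0,0,0,0,0,0,0,0
sp_shared_03,1,3,0,0,0,0,0,0,0,0,0
sp_shared_04,0,0,7,5,0,0,0,0,0,0,0
sp_shared_05,0,0,3,1,0,0,0,0,0,0,0
sp_shared_06,0,0,1,1,0,0,0,0,0,0,0
sp_shared_07,0,0,2,2,0,0,0,0,0,0,0
sp_shared_08,0,0,0,0,7,5,4,0,0,0,0
sp_shared_09,0,0,0,0,3,7,6,0,0,0,0
sp_shared_10,0,0,0,0,6,9,11,0,0,0,0
sp_shared_11,0,0,0,0,2,3,0,0,0,0,0
sp_shared_12,0,0,0,0,0,3,3,0,0,0,0
sp_shared_13,0,0,0,0,0,0,0,1,5,0,0
sp_shared_14,0,0,0,0,0,0,0,5,8,0,0
sp_shared_15,0,0,0,0,0,0,0,1,2,0,0
sp_shared_16,0,0,0,0,0,0,0,8,4,0,0
sp_shared_17,0,0,0,0,0,0,0,17,11,0,0
sp_shared_18,0,0,0,0,0,0,0,3,1,0,0
sp_shared_19,0,0,0,0,0,0,0,1,1,0,0
sp_shared_20,0,0,0,0,0,0,0,16,6,0,0
sp_shared_21,0,0,0,0,0,0,0,4,3,1,0
sp_shared_22,0,0,0,0,0,0,0,6,3,5,0
sp_shared_23,0,0,0,0,0,0,0,12,12,6,0
sp_shared_24,2,3,2,1,2,2,2,6,0,0,0
sp_shared_25,0,0,1,3,3,2,5,2,4,0,0
sp_shared_26,0,0,0,0,4,1,1,3,1,3,0
sp_shared_27,2,2,2,1,1,3,0,0,0,0,0
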