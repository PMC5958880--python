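name,ordinal,age_base,age_top,zone
Pueblo,0,295.0,292.5,Coyotean
Moran,1,292.5,290.5,Coyotean
Putnam,2,290.5,288.5,Coyotean
Admiral,3,288.5,286.5,Seymourian
Belle Plains,4,286.5,284.5,Seymourian
Clyde,5,284.5,282.5,Mitchellcreekian
Lueders,6,282.5,280.5,Mitchellcreekian
Arroyo,7,280.5,279.1,Redtankian
Vale,8,279.1,277.8,Redtankian
Choza,9,277.8,276.5,Redtankian
San Angelo,10,276.5,275.0,Littlecrotonian
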