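analyte,side,limit,unit
PM2.5,outdoor,20,ug/m3
PM10,outdoor,50,ug/m3
VOC,outdoor,80,ppb
NO2,outdoor,106,ppb
PM2.5,indoor,15,ug/m3
PM10,indoor,50,ug/m3
VOC,indoor,142,ppb
NO2,indoor,74,ppb
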