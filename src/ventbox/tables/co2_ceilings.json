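{
  "anti_covid": 700,
  "air_quality": 1000
}
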