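space_class,fb_l_s
high_aerosol,15
library_office,14
ordinary_public,10
minimum,5
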