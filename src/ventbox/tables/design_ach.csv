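space_type,ach_min,ach_max
auditorium,6,8
lecture_room,5,7
library,4,5
office,4,8
restaurant,8,12
cinema_room,5,8
gym,4,6
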