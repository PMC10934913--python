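age_group,gender,activity,rate_l_s
11-15,men,rest,0.0041
11-15,women,rest,0.0035
11-15,men,walking,0.0068
11-15,women,walking,0.0058
11-15,men,physical,0.0136
11-15,women,physical,0.0117
16-20,men,rest,0.0045
16-20,women,rest,0.0036
16-20,men,walking,0.0075
16-20,women,walking,0.0059
16-20,men,physical,0.0150
16-20,women,physical,0.0119
21-29,men,rest,0.0048
21-29,women,rest,0.0038
21-29,men,walking,0.0080
21-29,women,walking,0.0063
21-29,men,physical,0.0160
21-29,women,physical,0.0126
30-39,men,rest,0.0046
30-39,women,rest,0.0035
30-39,men,walking,0.0076
30-39,women,walking,0.0059
30-39,men,physical,0.0152
30-39,women,physical,0.0118
40-49,men,rest,0.0046
40-49,women,rest,0.0036
40-49,men,walking,0.0077
40-49,women,walking,0.0060
40-49,men,physical,0.0155
40-49,women,physical,0.0119
11-49,men,rest,0.0042
11-49,women,rest,0.0036
11-49,men,walking,0.00752
11-49,women,walking,0.00598
11-49,men,physical,0.01506
11-49,women,physical,0.01198
average,person,rest,0.00390
average,person,walking,0.00675
average,person,physical,0.01352
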