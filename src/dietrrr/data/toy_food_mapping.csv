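food_code,group_id,split_rule
11100000,dairy,dairy_fat
11200000,dairy,dairy_fat
23100000,G3,none
24100000,G4,none
25100000,G5,none
26100000,G6,none
27100000,G7,none
28100000,G8,none
31100000,G9,none
41100000,G10,none
42100000,G11,none
51100000,G12,none
53100000,G13,none
54100000,G14,none
55100000,G15,none
56100000,G16,none
57100000,grain,grain_fiber
58100000,G18,none
41200000,G19,none
57200000,grain,grain_fiber
61100000,G22,none
64100000,G23,none
71100000,G24,none
72100000,G25,none
73100000,G26,none
75100000,G27,none
82100000,G28,none
82200000,G29,none
83100000,G30,none
91100000,G31,none
92100000,G32,none
93100000,G33,none
95100000,G34,none
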