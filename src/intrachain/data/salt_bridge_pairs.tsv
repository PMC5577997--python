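species	chain	pair_label
C. hamatus	beta1	Glu184||Arg211
C. hamatus	beta1	Glu18||Lys118
C. hamatus	beta1	Asp114||Arg132
C. hamatus	beta1	Glu31||His36
C. hamatus	beta1	Asp191||Arg28
C. hamatus	beta1	Glu205||Lys45
C. hamatus	beta1	Asp213||Arg211
D. labrax	beta1	Glu184||Arg211
D. labrax	beta1	Glu18||Lys118
D. labrax	beta1	Asp114||Arg132
D. labrax	beta1	Glu31||His36
D. labrax	beta1	Asp191||Arg28
D. labrax	beta1	Asp114||His116
T. bernacchii	beta1	Glu184||Arg211
T. bernacchii	beta1	Glu18||Lys118
T. bernacchii	beta1	Asp114||Arg132
T. bernacchii	beta1	Glu31||His36
T. bernacchii	beta1	Asp191||Arg38
T. bernacchii	beta1	Glu205||Arg194
T. bernacchii	beta1	Asp150||Lys156
T. bernacchii	beta1	Asp191||Arg28
T. bernacchii	beta1	Asp133||Lys136
C. hamatus	beta2	Asp184||His189
C. hamatus	beta2	Asp90||Lys86
C. hamatus	beta2	Glu40||Lys37
C. hamatus	beta2	Asp18||Lys34
C. hamatus	beta2	Glu74||Lys68
C. hamatus	beta2	Asp33||Arg181
C. hamatus	beta2	Asp184||Arg153
C. hamatus	beta2	Asp190||Arg181
C. hamatus	beta2	Glu109||Lys41
C. hamatus	beta2	ASP 52||HIS 99
D. labrax	beta2	Asp184||His189
D. labrax	beta2	Asp90||Lys86
D. labrax	beta2	Glu40||Lys37
D. labrax	beta2	Asp18||Lys34
D. labrax	beta2	Glu74||Lys68
D. labrax	beta2	Asp33||Arg181
D. labrax	beta2	Asp184||Arg153
D. labrax	beta2	Glu166||Arg170
D. labrax	beta2	Asp11||Arg153
T. bernacchii	beta2	Asp184||His189
T. bernacchii	beta2	Glu40||Lys37
T. bernacchii	beta2	Asp18||Lys34
T. bernacchii	beta2	Asp33||Arg181
T. bernacchii	beta2	Asp184||Arg153
T. bernacchii	beta2	Glu109||Lys41
T. bernacchii	beta2	Glu186||His189
T. bernacchii	beta2	Asp31||Lys29
T. bernacchii	beta2	Glu58||Lys62
T. bernacchii	beta2	Glu109||Lys185
C. hamatus	beta5	Asp17||Lys33
C. hamatus	beta5	Glu67||Arg64
C. hamatus	beta5	Glu36||Arg186
C. hamatus	beta5	Glu117||Lys91
C. hamatus	beta5	Glu182||Arg183
D. labrax	beta5	Asp17||Lys33
D. labrax	beta5	Glu67||Arg64
D. labrax	beta5	Glu36||Arg186
D. labrax	beta5	Asp124||Lys7
D. labrax	beta5	Glu190||Arg157
T. bernacchii	beta5	Asp17||Lys33
T. bernacchii	beta5	Glu67||Arg64
T. bernacchii	beta5	Glu36||Arg186
T. bernacchii	beta5	Glu117||Lys91
T. bernacchii	beta5	Asp105||Arg107
T. bernacchii	beta5	Glu154||Arg157
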