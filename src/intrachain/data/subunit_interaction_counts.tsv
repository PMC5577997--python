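species	chain	hbonds	saltbridges
C. hamatus	beta1	164	7
C. hamatus	beta2	151	10
C. hamatus	beta5	168	5
D. labrax	beta1	169	6
D. labrax	beta2	150	9
D. labrax	beta5	167	5
T. bernacchii	beta1	169	9
T. bernacchii	beta2	158	10
T. bernacchii	beta5	176	6
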