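construct,state,separation_A,pathway_distance_A,barrier_kcal_mol
nqo13,closed,3.0,14.0,14.0
nqo13,open,8.0,14.0,6.0
nqo12,closed,3.0,22.0,15.0
nqo12,open,8.0,22.0,13.0
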