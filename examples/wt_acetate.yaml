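# Acid-driven proton-conduction assay, WT Nqo13 construct.
# Run with:  protoflux simulate --config examples/wt_acetate.yaml --out-dir results
preset: WT-Nqo13
assay: acetate
amount: 10.0     # mM potassium acetate added at t_add
t_add: 60.0      # s
t_nig: 540.0     # s, nigericin addition
t_end: 600.0     # s
seed: 1
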