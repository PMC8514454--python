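# Desk-scale Type-I screen: all six families, smallest and 20/20-equivalent
# size pairs, reduced concentration grid, 1000 replicates; classifies the
# robust test set (empirical Type-I <= 0.075 in every cell).
nsim: 1000
classify_robust: true
grids: []
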