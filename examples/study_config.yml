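# Example study configuration: rhythm analysis of an already-quantified
# expression table (two panels simulated from the published parameters).
expression_table: examples/example_expression.csv
alpha_anova: 0.05
alpha_cosinor: 0.005
ci_level: 0.99
out_dir: results/example_report
seed: 7
make_plots: false
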