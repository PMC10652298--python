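# Bundled demonstration configuration: simulated inputs with study-like
# structure, sized to complete in well under a minute on one CPU.

seed = 17

[simulate]
n_genes = 1200
n_cells_per_group = 12
homolog_coverage = 0.85
n_fly_background = 1200

[simulate.truth]
rho_true = 0.37
same_sign_frac_true = 0.69
enrichment_factor = 10.0
phtx_effect = 0.5
n_peak_only_genes = 242
n_deg_only_records = 300

[integrate]
fdr_max = 0.05

[concordance]
binom_method = "minlike"
p0 = 0.5

[xspecies]
top_n = 20
n_boot = 2000
keyword = "synaptic"
min_frac_expressed = 0.01
fly_cell_type = "perineurial_glia"

[quantal]
ttest = "welch"
alpha = 0.05
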