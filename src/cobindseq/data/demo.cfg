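# cobindseq demo: simulated two-chromosome 1-Mb genome, all defaults
# scaled down so a full run takes seconds.
seed = 7
simulate = true

sim_n_chromosomes = 2
sim_chrom_length = 500000
sim_n_sites = 150
sim_n_genes = 60
sim_enrichment = 30
sim_background_rate = 1.0
sim_nb_dispersion = 0.2
sim_caller_sensitivity = 0.9
sim_caller_fp_rate = 5.0
sim_caller_jitter_sd = 30

extension = 200
min_support = 2
min_length = 150
min_reads = 10
min_fc = 2.0
max_q = 0.01
pairing_distance = 250
half_window = 500
subwindow = 25
k = 3
motif = CTGN{6,8}WGATAR
seq_width = 200
max_masked = 150
max_gene_distance = 1000000
proximal_distance = 5000
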