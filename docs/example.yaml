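# Small worked example for the README: 40 candidate fathers, 60 offspring,
# 10-site panel excluding chr1/chr7, 800x depth.
seed: 7
n_fathers: 40
n_offspring: 60
chrom_names: [chr1, chr2, chr3, chr4, chr5, chr6, chr7, chr8, chr9, chr10, chr11, chr12]
chrom_length: 20000
sites_per_chrom: 100
n_panel_sites: 10
excluded_chroms: [chr1, chr7]
focal_father: father_017
depth_mean: 800.0
ibd_min_sites: 200
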