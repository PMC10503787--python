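# 5 Mb demonstration dataset: two 10-sib families per pedigree design,
# inflated mutation rate so a small genome still yields countable DNMs.
sim:
  genome_length: 5000000
  n_chroms: 2
  n_families: 2
  pedigree_type: three_gen_inbred
  sibs_per_clutch: 10
  true_mu: 2.0e-7
generation_time: 2.0
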