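{
  "non_rrna_reads": 27923,
  "protein_homolog_reads": 14680,
  "cog_assigned_reads": 6975
}
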