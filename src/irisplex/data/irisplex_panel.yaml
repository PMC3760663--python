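# Default IrisPlex six-SNP panel.
#
# The effect allele is the minor allele counted by the published prediction
# model; this orientation is transcribed from the model's source publications
# (externally sourced — it is not derivable from genotype data alone).
format: irisplex-panel-v1
snps:
  - {rs_id: rs12913832, gene: HERC2,   effect_allele: T, other_allele: C}
  - {rs_id: rs1800407,  gene: OCA2,    effect_allele: A, other_allele: G}
  - {rs_id: rs16891982, gene: SLC45A2, effect_allele: C, other_allele: G}
  - {rs_id: rs1393350,  gene: TYR,     effect_allele: A, other_allele: G}
  - {rs_id: rs12896399, gene: SLC24A4, effect_allele: G, other_allele: T}
  - {rs_id: rs12203592, gene: IRF4,    effect_allele: T, other_allele: C}
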