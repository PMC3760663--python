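# EXTERNALLY SOURCED parameter set.
#
# Multinomial-logistic coefficients of the published IrisPlex eye-colour
# model, transcribed by the package author from the model's source
# publications (Liu et al. 2009; Walsh et al. 2011). They are NOT derived
# or validated by this package and no test in this repository depends on
# them; they are provided so users can run the published model as-is.
# Reference category: brown. Effects are per effect-allele dosage in the
# panel order of irisplex_panel.yaml.
format: irisplex-params-v1
provenance: "externally sourced: transcribed from the published IrisPlex model papers"
reference_category: brown
panel: [rs12913832, rs1800407, rs16891982, rs1393350, rs12896399, rs12203592]
alpha:
  blue: 3.94
  intermediate: 0.65
beta:
  blue:
    rs12913832: -4.81
    rs1800407: 1.40
    rs16891982: -1.30
    rs1393350: 0.47
    rs12896399: -0.58
    rs12203592: 0.70
  intermediate:
    rs12913832: -1.79
    rs1800407: 0.87
    rs16891982: -0.50
    rs1393350: 0.27
    rs12896399: -0.03
    rs12203592: 0.73
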