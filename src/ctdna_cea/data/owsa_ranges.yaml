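# One-way sensitivity ranges for the tornado diagram.
#   - ARPI drug split varied over its full range (0 = all enzalutamide,
#     1 = all abiraterone)
#   - ctDNA predictive value varied between 0.65 and 0.95
#   - ctDNA analysis cost reduced to EUR 100 per sample
#   - drug prices decreased by 90% (generic-entry scenario) for the
#     on-patent / high-cost drugs
arpi_abi_share: [0.0, 1.0]
ctdna_ppv: [0.65, 0.95]
ctdna_cost_per_sample: [100.0, 350.0]
lines.enzalutamide.drug_cost_per_cycle: [215.0, 2150.0]
lines.abiraterone.drug_cost_per_cycle: [115.0, 1150.0]
lines.cabazitaxel.drug_cost_per_cycle: [380.0, 3800.0]
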