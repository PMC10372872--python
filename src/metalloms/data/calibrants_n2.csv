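# Default TW calibrant reference table, version 2023-01.
# Representative nitrogen-gas CCS values (Angstrom^2) for native-like charge
# states of the three common protein calibrants, compiled from published
# drift-tube N2 measurements. Intended as a starting point only: replace with
# your laboratory's preferred calibrant database for quantitative work, and
# always match the charge states actually observed.
protein,charge,mass_da,ccs_n2_a2
ubiquitin,4,8565.8,1090.0
ubiquitin,5,8565.8,1137.0
ubiquitin,6,8565.8,1525.0
cytochrome_c,6,12358.3,1393.0
cytochrome_c,7,12358.3,1513.0
cytochrome_c,8,12358.3,1845.0
beta_lactoglobulin,7,18363.3,1956.0
beta_lactoglobulin,8,18363.3,2003.0
beta_lactoglobulin,9,18363.3,2090.0
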