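entry,value,units
polysaccharide_cell_wall,7.16,mmol ATP/g DCW
amino_acid_synthesis,5.65,mmol ATP/g DCW
protein_polymerization,17.49,mmol ATP/g DCW
lipid,0.52,mmol ATP/g DCW
rna_nmp_formation,1.20,mmol ATP/g DCW
rna_polymerization,0.27,mmol ATP/g DCW
rna_mrna_turnover,0.30,mmol ATP/g DCW
dna_dnmp_formation,0.48,mmol ATP/g DCW
dna_polymerization,0.18,mmol ATP/g DCW
subtotal,33.23,mmol ATP/g DCW
transport_ammonium,8.43,mmol ATP/g DCW
transport_potassium,0.20,mmol ATP/g DCW
transport_phosphate,0.80,mmol ATP/g DCW
total,42.66,mmol ATP/g DCW
protein_term_atp,43.28,mmol ATP/g protein
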