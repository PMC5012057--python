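substrate,quantity,mean,sd,units
cellobiose,uptake_cellobiose,3.58,0.16,mmol/gDCW/h
cellobiose,ethanol,4.19,0.10,mmol/gDCW/h
cellobiose,acetate,2.63,0.86,mmol/gDCW/h
cellobiose,formate,1.77,0.01,mmol/gDCW/h
cellobiose,hydrogen,7.86,0.38,mmol/gDCW/h
cellobiose,valine,0.78,0.12,mmol/gDCW/h
cellobiose,lactate,0.18,0.01,mmol/gDCW/h
cellobiose,growth_rate,0.33,0.01,1/h
cellulose,uptake_glucose_equivalents,6.39,0.08,mmol/gDCW/h
cellulose,ethanol,2.63,0.03,mmol/gDCW/h
cellulose,acetate,3.40,0.15,mmol/gDCW/h
cellulose,formate,1.38,0.01,mmol/gDCW/h
cellulose,lactate,0.00,0.0,mmol/gDCW/h
cellulose,growth_rate,0.31,0.01,1/h
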