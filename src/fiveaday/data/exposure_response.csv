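exposure,outcome,unit_g,direction,rr,ci_low,ci_high
fruit,IHD,100,increase,0.86,0.79,0.95
fruit,ischemic_stroke,100,increase,0.65,0.55,0.79
fruit,lung_cancer,100,increase,0.93,0.89,0.97
fruit,esophageal_cancer,100,increase,0.87,0.78,0.97
fruit,T2D,100,increase,0.91,0.84,0.98
vegetables,IHD,100,increase,0.86,0.78,0.94
vegetables,ischemic_stroke,100,increase,0.87,0.79,0.97
legumes,IHD,50,increase,0.76,0.65,0.89
red_meat,colorectal_cancer,100,decrease,0.86,0.76,0.97
red_meat,T2D,100,decrease,0.80,0.68,0.97
processed_meat,IHD,50,decrease,0.56,0.39,0.97
processed_meat,colorectal_cancer,50,decrease,0.85,0.79,0.91
processed_meat,T2D,50,decrease,0.58,0.47,0.76
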