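scenario,parameter,observed
healthy_750mg,cmax_ng_ml,681
healthy_750mg,tmax_h,3
healthy_750mg,auc_ng_ml_h,7150
healthy_250mg,cmax_ng_ml,371
healthy_250mg,tmax_h,1.5
healthy_250mg,auc_ng_ml_h,2940
itraconazole,cmax_ratio,1.34
itraconazole,auc_ratio,1.71
rifampin,cmax_ratio,0.39
rifampin,auc_ratio,0.17
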