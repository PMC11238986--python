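model,n,h,e_raw,e_std,threshold,is_median
Bovine chromaffin cells,5,2,15,20,,False
Rat hippocampus/cortex,6,2,45,8,600,False
Xenopus oocytes,6,2,300,2,1500,False
Rat neurons,5,2,18,5,150,False
Mouse L-tk cells,8,1.2,9,0.3,300,False
Rat dentate granule cells,7,1.15,3.9,5,90,False
Rat embryo hippocampal neurons,7,2.8,300,4.8,900,False
Median values,,2,18,5,450,True
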