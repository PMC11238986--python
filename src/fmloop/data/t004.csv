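effect,range,component,e,h,a_f
GABA_A activity,Follicular-luteal-pregnancy,allosteric,18,2,0.4
alpha4 subunit expression,Withdrawal-luteal,withdrawal,1.8,6.5,0.4
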