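interaction,parameter,value
Double inhibition,e_x,28
Double inhibition,h_x,4.2
Self-limiting effect,e_k,25.57
Self-limiting effect,h_k,6.6
Self-limiting effect,alpha,0.48
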