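x,y,e,h,n,p,species,is_median
corticosterone,progesterone,1,4.2,6,< 0.001,chicken,False
corticosterone,testosterone,5,3.9,4,< 0.001,chicken,False
cortisol,testosterone,28,5.2,6,< 0.001,rabbit,False
cortisol,LH,28,2.4,13,< 0.001,swine,False
cortisol,progesterone,23,8,8,< 0.001,humans,False
cortisol,testosterone,22,6,10,< 0.001,men,False
cortisol,testosterone,48,2.4,71,< 0.001,men,False
progesterone,corticosterone,32,3.5,11,< 0.001,chicken,False
testosterone,cortisol,17,7.3,6,< 0.001,rabbit,False
testosterone,cortisol,58,7.5,12,< 0.001,rabbit,False
LH,cortisol,50,7.5,6,< 0.001,rabbit,False
LH,cortisol,51,4.1,12,< 0.001,rabbit,False
testosterone,cortisol,23,1.5,71,< 0.001,male humans,False
progesterone,cortisol,64,3.8,23,< 0.001,female humans,False
progesterone,cortisol,65,8,6,< 0.001,female humans,False
,,28,4.2,,,,True
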