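phase,steroid,tissue,concentration,provenance
Follicular,Progesterone,Plasma,1.5,measured
Follicular,Progesterone,Brain,,
Follicular,Allopregnanolone,Plasma,0.15,measured
Follicular,Allopregnanolone,Brain,2.4,ratio-estimated
Luteal,Progesterone,Plasma,10,measured
Luteal,Progesterone,Brain,41,measured
Luteal,Allopregnanolone,Plasma,1.2,measured
Luteal,Allopregnanolone,Brain,20,measured
Late pregnancy,Progesterone,Plasma,204,measured
Late pregnancy,Progesterone,Brain,,
Late pregnancy,Allopregnanolone,Plasma,16,measured
Late pregnancy,Allopregnanolone,Brain,260,ratio-estimated
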