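surface,load_N,rep1_mV,rep2_mV,rep3_mV,average_mV
rigid,0,126,131,122,126
rigid,10,223,220,210,217
rigid,20,314,302,297,304
rigid,30,395,379,388,387
rigid,40,466,452,461,459
rigid,50,527,515,524,522
rigid,60,600,591,596,595
rigid,70,670,663,663,665
rigid,80,737,731,744,737
rigid,90,803,790,795,796
rigid,100,859,846,845,850
flexible,0,128,129,131,129
flexible,10,236,240,235,237
flexible,20,343,352,343,346
flexible,30,442,445,443,443
flexible,40,549,535,534,539
flexible,50,632,625,630,629
flexible,60,713,708,710,710
flexible,70,786,791,784,787
flexible,80,858,865,857,860
flexible,90,937,941,935,938
flexible,100,1009,1010,1018,1012
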