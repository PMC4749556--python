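experiment,subject,bet_tp_at_75
1,AVT,0.676
1,AM,0.714
1,JDK,0.716
1,SH,0.682
1,MM,0.684
1,AC,0.685
1,MR,0.674
1,MK,0.658
1,RA,0.619
2,AVT,0.666
2,AM,0.713
2,JDK,0.746
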