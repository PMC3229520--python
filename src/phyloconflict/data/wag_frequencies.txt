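0.08662790866
0.04397200440
0.03908940391
0.05704510570
0.01930780193
0.03672810367
0.05805890581
0.08325180833
0.02443130244
0.04846600485
0.08620900862
0.06202860620
0.01950270195
0.03843190384
0.04576310458
0.06951790695
0.06101270610
0.01438590144
0.03527420353
0.07089560709
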