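0.5515710
0.5098480
0.7389980
1.0270400
0.9085980
1.5828500
1.4167200
0.3169540
0.1933350
0.3979150
0.9062650
0.8934960
0.2104940
1.4385500
3.3707900
2.1211100
0.1131330
0.2407350
2.0060100
0.6353460
0.1473040
0.5281910
3.0355000
0.4391570
0.5846650
2.1371500
0.1869790
0.4976710
5.3514200
0.6831620
0.1027110
0.6794890
1.2241900
0.5544130
1.1639200
0.3815330
0.2518490
5.4294200
0.2652560
1.5436400
0.9471980
1.1255600
3.9562900
0.5542360
0.1315280
3.0120100
0.1982210
0.0961621
0.1950810
3.9742300
2.0300600
0.0719167
1.0860000
0.1962460
0.0302949
0.6167830
6.1741600
0.8655840
0.9306760
0.0394370
0.0848047
0.4798550
0.1037540
0.0467304
0.4239840
1.0717600
0.3748660
0.1297670
0.3257110
0.1523350
0.0988179
0.0213520
0.3066740
0.2489720
0.1701350
0.3842870
0.0740339
0.3904820
0.3980200
0.1094040
1.4076600
0.5129840
0.7170700
0.5438330
1.0021400
5.4694700
0.3300520
4.2941100
0.1139170
0.8694890
3.8949000
1.5452600
0.0999208
0.9333720
1.0288700
0.8579280
0.2157370
0.2277100
0.3012810
0.5677170
0.5700250
0.1273950
0.1542630
2.5844300
0.3151240
0.0811339
0.6823550
0.7049390
0.8227650
0.1565570
0.1963030
0.5887310
0.2494100
0.0304501
0.0613037
0.3735580
0.1741000
0.0499310
0.2435700
1.3418200
0.2258330
0.3369830
0.1036040
0.1872470
0.1381900
0.4994620
0.8904320
0.4041410
0.6793710
0.6961980
0.7401690
0.4733070
0.2625690
3.8734400
0.1183580
3.1709700
0.3238320
4.2574600
1.0594700
0.0999288
0.3194400
1.4581600
0.2124830
0.4201700
7.8213000
0.2575550
4.8540200
2.1151700
0.4158440
0.3447390
0.3266220
0.6653090
0.3986180
1.8003400
0.9342760
0.0888360
0.5568960
0.9671300
1.3869800
0.1375050
0.1332640
0.3054340
1.1906300
0.1713290
0.4939050
1.5161200
0.5157060
0.4284370
2.0584500
0.1614440
0.5459310
0.1719030
1.5296400
6.4542800
0.6498920
1.6132800
0.7953840
0.1394050
0.2160460
0.3148870
4.3780200
0.5237420
0.7869930
0.2327390
0.1108640
0.2911480
1.3882300
2.4853900
0.3653690
0.3147300
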