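"x","y","fitted"
0.0736226975100551,48.6363681248747,49.0368456845128
0.438037657872288,54.1092766676977,51.4680694788796
0.638172561041753,49.771251402087,52.7603061577995
0.941773478876495,53.8669968998756,54.5317384416834
1.14530073535973,55.7441211096911,55.6351968199332
1.28113632675546,57.1489553265458,56.3926520651101
1.29921505335472,57.4711923343908,56.4807635395274
1.3975248360931,58.0194008628631,56.9006714964755
1.39796998127657,55.736960190903,56.902362914873
1.54289492067548,56.0470329770112,57.4509937553551
1.89471359084286,59.8347033395132,57.4027184183826
1.94638707851968,57.8842594516533,57.3751401166416
1.99908202475108,55.8608563944097,57.373855887973
2.26909349050884,56.7968530495932,57.7836138094186
2.27238721784777,57.2314693234899,57.7890510209629
2.88328103930244,60.9110312540567,59.9989104611643
3.12366641382041,60.28444978724,60.7465645236218
3.25825358138152,61.363963316088,60.6493087626004
3.54525968129868,58.9425013842732,60.1057746135913
3.70459706034869,59.923471499272,59.7586052174202
3.70798024232581,60.8528599395727,59.7504818283545
3.87478379030174,58.7168372739952,59.3210772837308
4.37151918872331,59.0814968695168,57.576285999397
4.38878439752052,56.7939868306846,57.5245104748828
4.43414198827331,57.2572202064266,57.3831199996436
4.50385937895567,57.0051199015482,57.1810334075903
4.5891577553834,55.1013827159265,56.9430965724511
4.66721003727034,58.2029268237752,56.7178796681285
4.69555811275808,56.1915181488983,56.6363076244736
4.75704926225934,56.9364083620405,56.4605896155842
5.54584787015835,54.5652325352817,54.5711499167129
5.68741195952894,53.8280684584388,54.0362185586214
6.31664399122065,51.1634846010573,49.6440547489549
6.43865120080665,49.0264821503968,48.7332094249056
6.64850856592032,47.3369277413524,47.057848420396
6.6981399468251,47.7806437786724,46.585039687904
6.82495503974975,43.9494897268191,45.5873661280151
6.83048953242455,44.4032805561541,45.5495315340381
6.97368029059364,43.9703050227114,44.7147882987916
7.00265102002249,44.4852643259842,44.5860095571398
7.05165378626335,47.0510552423209,44.4123444190848
7.44762155907817,42.6902622230916,44.4894354116063
7.58087740085374,43.2010012960495,43.7758072405116
7.61139701990353,46.4349039003962,43.6316490145883
7.73956048555963,42.6322922746412,42.9910299347765
7.78383497073762,44.6562671383909,42.7964633578355
7.80729031021968,41.2286874404892,42.6988493079079
7.86064305276954,42.4945446657847,42.4822043945192
7.86924377502138,40.9751346694585,42.4526053917796
8.04764357496802,41.6003612680046,41.8439855656897
8.2276161327083,43.4192556767133,41.3476916244206
8.27631171992582,38.1492680395314,41.2345721231592
8.32259801395201,42.3493042813488,41.0739512873339
8.32678196057837,41.9449929391002,41.0580101092231
8.58597919911382,39.6783632451267,39.9942372880053
8.93121121322198,37.410852152313,38.776847638219
9.26764988848602,40.175104683658,38.7696014851069
9.6750973243421,39.0192371189163,39.8977409052109
9.70698024394903,40.5647350307909,40.0329421273874
9.75622351636756,40.1807104934258,40.2540020642659
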