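sample_id,tissue,gene,zt_h,rq
hypothalamus_ZT0_f01,hypothalamus,preproghrelin,0.0,1.7497970552676003
hypothalamus_ZT0_f02,hypothalamus,preproghrelin,0.0,0.4651051746419268
hypothalamus_ZT0_f03,hypothalamus,preproghrelin,0.0,3.4115713637583274
hypothalamus_ZT0_f04,hypothalamus,preproghrelin,0.0,2.6212127335422233
hypothalamus_ZT0_f05,hypothalamus,preproghrelin,0.0,2.725199927163927
hypothalamus_ZT0_f06,hypothalamus,preproghrelin,0.0,3.9235782267101977
hypothalamus_ZT4_f01,hypothalamus,preproghrelin,4.0,0.7471908332973858
hypothalamus_ZT4_f02,hypothalamus,preproghrelin,4.0,1.9477272958075034
hypothalamus_ZT4_f03,hypothalamus,preproghrelin,4.0,1.3513831715708946
hypothalamus_ZT4_f04,hypothalamus,preproghrelin,4.0,2.0064731433518253
hypothalamus_ZT4_f05,hypothalamus,preproghrelin,4.0,1.6415181148517768
hypothalamus_ZT4_f06,hypothalamus,preproghrelin,4.0,1.4086472903569605
hypothalamus_ZT8_f01,hypothalamus,preproghrelin,8.0,2.229907417627139
hypothalamus_ZT8_f02,hypothalamus,preproghrelin,8.0,0.7879720083804533
hypothalamus_ZT8_f03,hypothalamus,preproghrelin,8.0,0.23288601338713466
hypothalamus_ZT8_f04,hypothalamus,preproghrelin,8.0,1.1162265612527795
hypothalamus_ZT8_f05,hypothalamus,preproghrelin,8.0,3.2508527155922886
hypothalamus_ZT8_f06,hypothalamus,preproghrelin,8.0,3.2431038891773554
hypothalamus_ZT12_f01,hypothalamus,preproghrelin,12.0,2.150192421833219
hypothalamus_ZT12_f02,hypothalamus,preproghrelin,12.0,4.210705822834883
hypothalamus_ZT12_f03,hypothalamus,preproghrelin,12.0,5.0008248396476205
hypothalamus_ZT12_f04,hypothalamus,preproghrelin,12.0,3.004662475601619
hypothalamus_ZT12_f05,hypothalamus,preproghrelin,12.0,2.7968798555792653
hypothalamus_ZT12_f06,hypothalamus,preproghrelin,12.0,2.9143748898547757
hypothalamus_ZT16_f01,hypothalamus,preproghrelin,16.0,4.645270493770321
hypothalamus_ZT16_f02,hypothalamus,preproghrelin,16.0,4.0951337561064225
hypothalamus_ZT16_f03,hypothalamus,preproghrelin,16.0,3.2694302925035457
hypothalamus_ZT16_f04,hypothalamus,preproghrelin,16.0,3.3248364260258954
hypothalamus_ZT16_f05,hypothalamus,preproghrelin,16.0,2.964758282302285
hypothalamus_ZT16_f06,hypothalamus,preproghrelin,16.0,3.301310360724645
hypothalamus_ZT20_f01,hypothalamus,preproghrelin,20.0,2.9603960878438116
hypothalamus_ZT20_f02,hypothalamus,preproghrelin,20.0,3.4164972292141145
hypothalamus_ZT20_f03,hypothalamus,preproghrelin,20.0,5.502350467846554
hypothalamus_ZT20_f04,hypothalamus,preproghrelin,20.0,3.670260648662431
hypothalamus_ZT20_f05,hypothalamus,preproghrelin,20.0,3.349769637009497
hypothalamus_ZT20_f06,hypothalamus,preproghrelin,20.0,3.4872621376842257
hypothalamus_ZT24_f01,hypothalamus,preproghrelin,24.0,1e-06
hypothalamus_ZT24_f02,hypothalamus,preproghrelin,24.0,2.135664065239003
hypothalamus_ZT24_f03,hypothalamus,preproghrelin,24.0,1.6205162487797726
hypothalamus_ZT24_f04,hypothalamus,preproghrelin,24.0,3.0219849306705697
hypothalamus_ZT24_f05,hypothalamus,preproghrelin,24.0,2.260968502795356
hypothalamus_ZT24_f06,hypothalamus,preproghrelin,24.0,2.828950195262026
gastrointestinal_tract_ZT0_f01,gastrointestinal_tract,preproghrelin,0.0,2.3928908978368053
gastrointestinal_tract_ZT0_f02,gastrointestinal_tract,preproghrelin,0.0,2.0906341473693484
gastrointestinal_tract_ZT0_f03,gastrointestinal_tract,preproghrelin,0.0,3.9705316259319923
gastrointestinal_tract_ZT0_f04,gastrointestinal_tract,preproghrelin,0.0,4.735337992050885
gastrointestinal_tract_ZT0_f05,gastrointestinal_tract,preproghrelin,0.0,3.4235570493406873
gastrointestinal_tract_ZT0_f06,gastrointestinal_tract,preproghrelin,0.0,3.933366187722794
gastrointestinal_tract_ZT4_f01,gastrointestinal_tract,preproghrelin,4.0,0.9996216631514988
gastrointestinal_tract_ZT4_f02,gastrointestinal_tract,preproghrelin,4.0,1.8595936427474427
gastrointestinal_tract_ZT4_f03,gastrointestinal_tract,preproghrelin,4.0,0.7496257844461318
gastrointestinal_tract_ZT4_f04,gastrointestinal_tract,preproghrelin,4.0,0.9700649552854606
gastrointestinal_tract_ZT4_f05,gastrointestinal_tract,preproghrelin,4.0,1e-06
gastrointestinal_tract_ZT4_f06,gastrointestinal_tract,preproghrelin,4.0,0.1041242686926046
gastrointestinal_tract_ZT8_f01,gastrointestinal_tract,preproghrelin,8.0,3.5687163854003487
gastrointestinal_tract_ZT8_f02,gastrointestinal_tract,preproghrelin,8.0,1.246049487859569
gastrointestinal_tract_ZT8_f03,gastrointestinal_tract,preproghrelin,8.0,1.20693397371054
gastrointestinal_tract_ZT8_f04,gastrointestinal_tract,preproghrelin,8.0,2.190174978660453
gastrointestinal_tract_ZT8_f05,gastrointestinal_tract,preproghrelin,8.0,2.12020589200546
gastrointestinal_tract_ZT8_f06,gastrointestinal_tract,preproghrelin,8.0,0.4527963851706399
gastrointestinal_tract_ZT12_f01,gastrointestinal_tract,preproghrelin,12.0,3.4647241847177117
gastrointestinal_tract_ZT12_f02,gastrointestinal_tract,preproghrelin,12.0,4.485042976077733
gastrointestinal_tract_ZT12_f03,gastrointestinal_tract,preproghrelin,12.0,5.046943125722919
gastrointestinal_tract_ZT12_f04,gastrointestinal_tract,preproghrelin,12.0,4.236340849455255
gastrointestinal_tract_ZT12_f05,gastrointestinal_tract,preproghrelin,12.0,2.5994577207645744
gastrointestinal_tract_ZT12_f06,gastrointestinal_tract,preproghrelin,12.0,5.357353762054001
gastrointestinal_tract_ZT16_f01,gastrointestinal_tract,preproghrelin,16.0,8.199426297352538
gastrointestinal_tract_ZT16_f02,gastrointestinal_tract,preproghrelin,16.0,6.4046024579512935
gastrointestinal_tract_ZT16_f03,gastrointestinal_tract,preproghrelin,16.0,7.47579096254044
gastrointestinal_tract_ZT16_f04,gastrointestinal_tract,preproghrelin,16.0,6.4396076273927925
gastrointestinal_tract_ZT16_f05,gastrointestinal_tract,preproghrelin,16.0,6.6299930904340085
gastrointestinal_tract_ZT16_f06,gastrointestinal_tract,preproghrelin,16.0,6.108651148401599
gastrointestinal_tract_ZT20_f01,gastrointestinal_tract,preproghrelin,20.0,6.044118839114885
gastrointestinal_tract_ZT20_f02,gastrointestinal_tract,preproghrelin,20.0,7.476483293957981
gastrointestinal_tract_ZT20_f03,gastrointestinal_tract,preproghrelin,20.0,5.954635825989634
gastrointestinal_tract_ZT20_f04,gastrointestinal_tract,preproghrelin,20.0,5.34548270693229
gastrointestinal_tract_ZT20_f05,gastrointestinal_tract,preproghrelin,20.0,7.337598565562024
gastrointestinal_tract_ZT20_f06,gastrointestinal_tract,preproghrelin,20.0,6.07739492665738
gastrointestinal_tract_ZT24_f01,gastrointestinal_tract,preproghrelin,24.0,3.7945649775996926
gastrointestinal_tract_ZT24_f02,gastrointestinal_tract,preproghrelin,24.0,2.939220451834494
gastrointestinal_tract_ZT24_f03,gastrointestinal_tract,preproghrelin,24.0,1.917390556870476
gastrointestinal_tract_ZT24_f04,gastrointestinal_tract,preproghrelin,24.0,3.1036908509470176
gastrointestinal_tract_ZT24_f05,gastrointestinal_tract,preproghrelin,24.0,2.399233813000415
gastrointestinal_tract_ZT24_f06,gastrointestinal_tract,preproghrelin,24.0,4.524707170028247
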