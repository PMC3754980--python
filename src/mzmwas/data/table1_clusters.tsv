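cluster	mz	correlated_features
1	186.221	308.857, 376.844, 324.831, 392.818, 347.139, 289.945, 213.909, 243.037, 353.103, 344.184, 348.155, 341.192, 214.062
1	208.096	289.945, 353.103, 341.192, 328.192, 229.096
1	310.187	323.093, 243.037
1	328.192	289.945, 322.189
1	341.192	289.945, 229.096, 208.096, 310.187
1	341.192	213.909, 186.221
1	344.184	229.096, 186.221, 213.909
1	353.103	324.831, 376.844, 308.857, 213.909
2	448.303	449.306, 450.318
2	449.306	448.303, 450.318
2	450.318	451.322, 452.326, 472.300, 414.297, 433.311, 432.308, 473.303, 415.301, 448.303, 453.328, 449.306
2	472.300	451.322, 450.318, 452.326, 414.297, 473.303, 433.311, 415.301, 432.308, 453.328, 434.315
2	656.792	646.762, 147.977, 642.815, 590.801, 588.804, 640.818, 648.760, 658.788, 567.106, 708.806, 672.767, 557.148, 698.777, 551.166, 579.145, 306.048, 630.790, 632.786, 578.776
3	244.189	245.193, 453.366
3	245.193	244.189, 453.366
4	328.137	334.157
4	334.157	328.137
Independent	220.556	223.566, 171.552, 306.048, 551.166, 312.068, 174.562
Independent	293.586	293.084, 290.074, 386.626, 383.616, 386.126, 385.624, 383.114, 200.043, 203.053
Independent	322.189	232.051
Independent	416.211	476.262, 437.190, 432.236, 415.209, 237.116
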