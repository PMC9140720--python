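sex,level,x,lx
female,1,1,0.78138
female,1,2,0.69686
female,1,3,0.63673
female,1,5,0.55
female,1,10,0.47901
female,1,15,0.43551
female,1,20,0.40408
female,2,1,0.80157
female,2,2,0.72337
female,2,3,0.66715
female,2,5,0.58506
female,2,10,0.51688
female,2,15,0.47459
female,2,20,0.44376
female,3,1,0.81956
female,3,2,0.74726
female,3,3,0.6948
female,3,5,0.61739
female,3,10,0.55227
female,3,15,0.51145
female,3,20,0.48145
female,4,1,0.83566
female,4,2,0.76885
female,4,3,0.71999
female,4,5,0.64721
female,4,10,0.58528
female,4,15,0.5461
female,4,20,0.51712
female,5,1,0.85013
female,5,2,0.78842
female,5,3,0.74296
female,5,5,0.67469
female,5,10,0.61604
female,5,15,0.57862
female,5,20,0.55078
female,6,1,0.86316
female,6,2,0.80618
female,6,3,0.76394
female,6,5,0.70004
female,6,10,0.64465
female,6,15,0.60906
female,6,20,0.58244
female,7,1,0.87494
female,7,2,0.82234
female,7,3,0.78312
female,7,5,0.72341
female,7,10,0.67125
female,7,15,0.63752
female,7,20,0.61217
female,8,1,0.8856
female,8,2,0.83705
female,8,3,0.80067
female,8,5,0.74496
female,8,10,0.69595
female,8,15,0.66408
female,8,20,0.64002
female,9,1,0.89527
female,9,2,0.85047
female,9,3,0.81675
female,9,5,0.76484
female,9,10,0.71888
female,9,15,0.68883
female,9,20,0.66607
female,10,1,0.90406
female,10,2,0.86272
female,10,3,0.83148
female,10,5,0.78316
female,10,10,0.74014
female,10,15,0.71189
female,10,20,0.69041
female,11,1,0.91206
female,11,2,0.87392
female,11,3,0.84499
female,11,5,0.80006
female,11,10,0.75985
female,11,15,0.73333
female,11,20,0.71311
female,12,1,0.91935
female,12,2,0.88416
female,12,3,0.85738
female,12,5,0.81563
female,12,10,0.77811
female,12,15,0.75326
female,12,20,0.73426
female,13,1,0.926
female,13,2,0.89354
female,13,3,0.86876
female,13,5,0.83
female,13,10,0.79501
female,13,15,0.77177
female,13,20,0.75395
female,14,1,0.94712
female,14,2,0.92353
female,14,3,0.90536
female,14,5,0.87663
female,14,10,0.85035
female,14,15,0.8327
female,14,20,0.81907
female,15,1,0.96203
female,15,2,0.94491
female,15,3,0.93162
female,15,5,0.91046
female,15,10,0.89094
female,15,15,0.87773
female,15,20,0.86747
female,16,1,0.97266
female,16,2,0.96022
female,16,3,0.95054
female,16,5,0.93502
female,16,10,0.92061
female,16,15,0.91082
female,16,20,0.90318
female,17,1,0.98026
female,17,2,0.97124
female,17,3,0.96418
female,17,5,0.95284
female,17,10,0.94226
female,17,15,0.93504
female,17,20,0.9294
female,18,1,0.98573
female,18,2,0.97918
female,18,3,0.97405
female,18,5,0.96578
female,18,10,0.95803
female,18,15,0.95274
female,18,20,0.94859
female,19,1,0.98968
female,19,2,0.98492
female,19,3,0.98119
female,19,5,0.97516
female,19,10,0.96951
female,19,15,0.96564
female,19,20,0.9626
female,20,1,0.99252
female,20,2,0.98907
female,20,3,0.98636
female,20,5,0.98198
female,20,10,0.97786
female,20,15,0.97503
female,20,20,0.97281
female,21,1,0.99458
female,21,2,0.99208
female,21,3,0.99011
female,21,5,0.98692
female,21,10,0.98392
female,21,15,0.98186
female,21,20,0.98024
female,22,1,0.99607
female,22,2,0.99425
female,22,3,0.99282
female,22,5,0.99051
female,22,10,0.98833
female,22,15,0.98683
female,22,20,0.98565
female,23,1,0.99715
female,23,2,0.99583
female,23,3,0.99479
female,23,5,0.99311
female,23,10,0.99152
female,23,15,0.99043
female,23,20,0.98958
female,24,1,0.99793
female,24,2,0.99698
female,24,3,0.99622
female,24,5,0.995
female,24,10,0.99385
female,24,15,0.99305
female,24,20,0.99243
both,1,1,0.76706
both,1,2,0.67824
both,1,3,0.61554
both,1,5,0.52588
both,1,10,0.45329
both,1,15,0.40919
both,1,20,0.37753
both,2,1,0.78838
both,2,2,0.70601
both,2,3,0.6472
both,2,5,0.56201
both,2,10,0.49192
both,2,15,0.44879
both,2,20,0.41752
both,3,1,0.80742
both,3,2,0.73111
both,3,3,0.67608
both,3,5,0.59546
both,3,10,0.52822
both,3,15,0.48636
both,3,20,0.45577
both,4,1,0.82448
both,4,2,0.75385
both,4,3,0.70246
both,4,5,0.62643
both,4,10,0.56224
both,4,15,0.52188
both,4,20,0.49217
both,5,1,0.83984
both,5,2,0.77449
both,5,3,0.72659
both,5,5,0.65507
both,5,10,0.59406
both,5,15,0.55536
both,5,20,0.52668
both,6,1,0.85369
both,6,2,0.79326
both,6,3,0.74867
both,6,5,0.68157
both,6,10,0.62377
both,6,15,0.58683
both,6,20,0.5593
both,7,1,0.86622
both,7,2,0.81036
both,7,3,0.76889
both,7,5,0.70606
both,7,10,0.65148
both,7,15,0.61635
both,7,20,0.59005
both,8,1,0.87757
both,8,2,0.82596
both,8,3,0.78743
both,8,5,0.7287
both,8,10,0.67729
both,8,15,0.644
both,8,20,0.61895
both,9,1,0.88788
both,9,2,0.8402
both,9,3,0.80444
both,9,5,0.74961
both,9,10,0.7013
both,9,15,0.66984
both,9,20,0.64608
both,10,1,0.89725
both,10,2,0.85322
both,10,3,0.82005
both,10,5,0.76893
both,10,10,0.72362
both,10,15,0.69397
both,10,20,0.67149
both,11,1,0.90579
both,11,2,0.86513
both,11,3,0.83438
both,11,5,0.78678
both,11,10,0.74436
both,11,15,0.71647
both,11,20,0.69526
both,12,1,0.91357
both,12,2,0.87603
both,12,3,0.84754
both,12,5,0.80326
both,12,10,0.7636
both,12,15,0.73742
both,12,20,0.71745
both,13,1,0.92067
both,13,2,0.88602
both,13,3,0.85964
both,13,5,0.81848
both,13,10,0.78145
both,13,15,0.75692
both,13,20,0.73815
both,14,1,0.94326
both,14,2,0.91804
both,14,3,0.89863
both,14,5,0.86801
both,14,10,0.84007
both,14,15,0.82135
both,14,20,0.8069
both,15,1,0.95925
both,15,2,0.9409
both,15,3,0.92669
both,15,5,0.90408
both,15,10,0.88325
both,15,15,0.86918
both,15,20,0.85827
both,16,1,0.97064
both,16,2,0.9573
both,16,3,0.94693
both,16,5,0.93032
both,16,10,0.91492
both,16,15,0.90446
both,16,20,0.89631
both,17,1,0.9788
both,17,2,0.96912
both,17,3,0.96155
both,17,5,0.9494
both,17,10,0.93807
both,17,15,0.93034
both,17,20,0.92431
both,18,1,0.98467
both,18,2,0.97764
both,18,3,0.97213
both,18,5,0.96326
both,18,10,0.95496
both,18,15,0.94928
both,18,20,0.94484
both,19,1,0.98891
both,19,2,0.9838
both,19,3,0.97979
both,19,5,0.97333
both,19,10,0.96726
both,19,15,0.96311
both,19,20,0.95985
both,20,1,0.99196
both,20,2,0.98826
both,20,3,0.98534
both,20,5,0.98064
both,20,10,0.97621
both,20,15,0.97318
both,20,20,0.9708
both,21,1,0.99418
both,21,2,0.99148
both,21,3,0.98937
both,21,5,0.98594
both,21,10,0.98272
both,21,15,0.98051
both,21,20,0.97877
both,22,1,0.99578
both,22,2,0.99382
both,22,3,0.99229
both,22,5,0.9898
both,22,10,0.98746
both,22,15,0.98584
both,22,20,0.98458
both,23,1,0.99694
both,23,2,0.99552
both,23,3,0.9944
both,23,5,0.9926
both,23,10,0.99089
both,23,15,0.98972
both,23,20,0.9888
both,24,1,0.99778
both,24,2,0.99675
both,24,3,0.99594
both,24,5,0.99463
both,24,10,0.99339
both,24,15,0.99254
both,24,20,0.99187
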