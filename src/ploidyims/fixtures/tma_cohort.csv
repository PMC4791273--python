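id,sex,age,group,ploidy,T,N,M,G,UICC,survival_months,status,ip
P01,m,59,normal,,,,,,,,,0.1022
P02,m,58,normal,,,,,,,,,0.0881
P03,w,78,normal,,,,,,,,,0.0052
P04,m,57,normal,,,,,,,,,0.0459
P05,w,52,normal,,,,,,,,,0.0018
P06,m,74,normal,,,,,,,,,0.0099
P07,m,47,normal,,,,,,,,,0.1199
P08,w,51,normal,,,,,,,,,0.0330
P09,m,66,normal,,,,,,,,,0.0038
P10,w,74,normal,,,,,,,,,0.1991
P11,m,59,tumor,diploid,3,0,0,2,1,90.0,alive,0.0020
P12,w,61,tumor,diploid,4,0,0,2,1,154.0,alive,0.2673
P13,w,75,tumor,diploid,3,0,0,2,1,57.6,dead,0.2191
P14,m,58,tumor,diploid,3,0,0,2,1,40.8,dead,0.5336
P15,w,78,tumor,diploid,4,0,0,2,1,50.4,dead,0.4410
P16,m,77,tumor,diploid,2,1,0,3,2,114.0,alive,0.2467
P17,m,57,tumor,diploid,3,1,0,2,2,64.8,alive,0.4448
P18,w,52,tumor,diploid,2,1,0,2,2,142.0,alive,0.2371
P19,w,73,tumor,diploid,4,1,0,3,2,18.0,dead,0.2715
P20,m,74,tumor,aneuploid,3,0,0,2,1,142.0,alive,0.3007
P21,m,47,tumor,aneuploid,3,0,0,3,1,133.0,alive,0.1592
P22,w,74,tumor,aneuploid,3,0,0,2,1,176.0,alive,0.3615
P23,w,72,tumor,aneuploid,3,0,0,2,1,27.6,dead,0.7899
P24,m,64,tumor,aneuploid,3,0,0,3,1,55.2,dead,0.4529
P25,w,51,tumor,aneuploid,3,1,0,2,2,109.0,alive,0.2003
P26,m,66,tumor,aneuploid,4,1,0,3,2,145.0,alive,0.0780
P27,w,74,tumor,aneuploid,3,1,0,3,2,10.8,dead,0.5090
P28,w,63,tumor,aneuploid,3,1,0,2,2,27.6,dead,0.6380
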