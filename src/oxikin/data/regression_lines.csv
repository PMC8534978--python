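sample,method,slope,intercept,r_squared
OA,arrhenius,-6.085,15.914,0.9585
CA+OA,arrhenius,-7.9738,20.55,0.9792
TBHQ+OA,arrhenius,-6.8938,17.867,0.9876
OA,eyring,-5.6975,8.9535,0.9528
TBHQ+OA,eyring,-6.5083,10.912,0.9860
CA+OA,eyring,-7.5879,13.594,0.9770
OA,fwo,-2.7636,6.2864,0.9965
CA+OA,fwo,-2.8881,6.454,0.9883
TBHQ+OA,fwo,-2.8294,6.3863,0.9960
OA,kas,-2.3126,-0.0147,0.9960
CA+OA,kas,-2.4308,0.1407,0.9853
TBHQ+OA,kas,-2.3751,0.0789,0.9952
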