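"id","frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]","offset [photon]","bkgstd [photon]","uncertainty [nm]"
1,1,100.0,200.0,148.7,1202.5,98.2,18.4,12.3
2,1,110.0,210.0,151.2,980.1,101.7,21.0,14.8
3,2,500.0,500.0,139.9,2203.8,99.5,17.2,9.1
4,2,742.5,1288.0,160.3,760.4,103.1,25.6,18.9
5,3,1503.2,330.6,145.0,1555.0,97.8,19.3,10.7
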