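state,DEF,FOS#2,FOS#3,FOS#>=4,FOS+1,FOS+2,FOS+3,OFF,P,E
SER,52.5,45.3,,,,,,,0.7,1.4
DEF,28.9,,42.8,18.3,,,,,1.6,8.4
FOS#2,,,,,77.2,,,,3.7,19.1
FOS#3,,,,,76.1,,,,6.6,17.3
FOS#>=4,,,,,73.8,,,,7.4,18.9
FOS+1,,,,,,61.5,,,5.4,33.1
FOS+2,,,,,,,68.2,,4.7,27.1
FOS+3,,,,,,,,68.8,5.4,25.8
OFF,,,,,,,,69.9,4.3,25.7
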