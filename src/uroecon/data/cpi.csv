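year,index
2014,96.5
2015,98.0
2016,100.0
2017,102.9
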