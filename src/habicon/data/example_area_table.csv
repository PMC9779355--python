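class,label,present_2020,ssp245_2030,ssp585_2030,ssp245_2050,ssp585_2050
1,marginal,2668,2059,1555,1883,1428
2,moderate,764,558,450,467,450
3,most,1237,853,581,1035,529
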