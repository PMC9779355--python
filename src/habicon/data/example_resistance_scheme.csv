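factor,kind,r10,r20,r30,r40,r50,weight
LUCC,categorical,High coverage of grassland,Low coverage of grassland,Cropland;Forest;Middle coverage of grassland;Bareland,Water area,Construction land,32.4
Bio1,continuous,-16..-6,-6..-4,-4..-2,-2..1,1..8,21.4
Bio3,continuous,-25..32,32..35,35..37,37..39,39..45,13.1
Bio7,continuous,36..38,34..36,38..40,30..34,40..43,12.7
Bio15,continuous,80..95,95..100,100..105,105..110,110..130,10.9
Bio16,continuous,110..180,180..220,220..235,235..250,250..408,5.6
Bio19,continuous,2..8,8..12,12..16,16..21,21..36,2.6
DW,continuous,0..5000,5000..10000,10000..15000,15000..20000,20000..50000,0.5
DH,continuous,0..5000,5000..10000,10000..15000,15000..20000,20000..50000,0.4
DR,continuous,0..5000,5000..10000,10000..15000,15000..20000,20000..70000,0.2
SLO,continuous,0..3,3..9,9..15,15..21,21..26,0.2
NPP,continuous,0..80,80..170,170..280,280..528,528..615,0.1
DEM,continuous,4500..5000,4000..4500,3500..4000,5000..6430,2000..3500,0.1
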