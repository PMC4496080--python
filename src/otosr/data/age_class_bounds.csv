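age_class,age_min_ma,age_max_ma
quaternary,0,2.58
neogene,2.58,23.03
paleogene,23.03,66
tertiary,2.58,66
cretaceous,66,145
jurassic,145,201.4
triassic,201.4,251.9
permian,251.9,298.9
carboniferous,298.9,358.9
devonian,358.9,419.2
silurian,419.2,443.8
ordovician,443.8,485.4
cambrian,485.4,538.8
ediacaran,538.8,635
cryogenian,635,720
tonian,720,1000
stenian,1000,1200
ectasian,1200,1400
calymmian,1400,1600
statherian,1600,1800
orosirian,1800,2050
rhyacian,2050,2300
siderian,2300,2500
neoarchean,2500,2800
mesoarchean,2800,3200
paleoarchean,3200,3600
eoarchean,3600,4000
precambrian,541,4000
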