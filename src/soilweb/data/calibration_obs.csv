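pool,value,sd
bacteria,15.1,3.02
fungi,15.1,3.02
mycorrhiza,160,32
bacterivores,0.1,0.02
fungivores,0.8,0.16
detritivores,0.6,0.12
engineers,0.2,0.04
herbivores,0.2,0.04
predators,0.4,0.04
litter,2680,335
som,11470,1433.75
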