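consumer,substrate,k_s
bacteria,litter,13400
bacteria,som,57350
fungi,litter,5360
fungi,som,22940
bacterivores,bacteria,15.1
fungivores,fungi,15.1
fungivores,mycorrhiza,160
detritivores,litter,2680
detritivores,som,11470
engineers,litter,2680
engineers,som,11470
herbivores,roots,400
predators,bacterivores,0.1
predators,fungivores,0.8
predators,detritivores,0.6
predators,engineers,0.2
predators,herbivores,0.2
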