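guild,lower,upper
bacteria,1,3
fungi,0,3
mycorrhiza,1,3
bacterivores,0,2
fungivores,0,2
detritivores,0,0.5
engineers,0,0.5
herbivores,0,0.5
predators,0,0.5
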