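guild,g_max,r,d,f_faec,m_faec,cn,p_m_cn,p_m_rec,t_min,t_opt,t_max,q10,size_class
bacteria,2.0,0.008,0.010,0.0,0.0,5,0.8,0.8,0,25,40,2,bacteria
fungi,1.5,0.007,0.010,0.0,0.0,10,0.2,0.3,0,20,40,2,micro
mycorrhiza,2.0,0.0008,0.0025,0.0,0.0,10,0.0,0.0,0,20,40,2,micro
bacterivores,1.0,0.010,0.010,0.3,0.0,6,0.0,0.0,0,20,35,2,micro
fungivores,1.0,0.010,0.010,0.3,0.0,6,0.0,0.0,0,20,35,2,micro
detritivores,0.25,0.010,0.005,0.5,0.5,6,0.3,0.3,0,20,35,2,meso
engineers,0.25,0.005,0.002,0.5,0.5,6,0.3,0.3,0,20,35,2,macro
herbivores,0.25,0.010,0.005,0.3,0.0,6,0.0,0.0,0,20,35,2,meso
predators,0.25,0.010,0.005,0.2,0.0,6,0.0,0.0,0,20,35,2,meso
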