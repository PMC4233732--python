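muscle,mass_g,fibre_length_cm,pcsa_cm2,max_force_n
superficial masseter,2.0,0.8,2.4,60.9
posterior deep masseter,0.3,0.7,0.4,10.3
ant. zygomaticomandibularis,0.5,0.8,0.6,15.0
post. zygomaticomandibularis,0.3,0.7,0.4,10.5
temporalis,1.1,0.8,1.5,37.1
medial pterygoid,1.5,0.6,2.5,62.3
lateral pterygoid,0.3,0.3,0.4,9.8
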