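group,n,h_mid_mean,h_mid_sd,h_orb_mean,h_orb_sd
surgical,16,39.0,6.9,-5.9,5.7
nonsurgical,27,27.7,4.6,10.2,6.3
severe_cluster,16,38.6,7.1,-6.7,4.7
mild_cluster,27,28.0,4.9,10.6,5.5
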