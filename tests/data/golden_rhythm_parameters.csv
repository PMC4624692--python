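tissue,gene,n,mesor,se_mesor,amplitude,se_amplitude,amplitude_ci_low,amplitude_ci_high,ci_level,acrophase_h,se_acrophase_h,rss
gastrointestinal_tract,preproghrelin,42,3.8767504228419662,0.14043619363591311,3.1335553434285157,0.20986614783932678,2.565256034920336,3.7018546519366953,0.99,17.29575045480346,0.22754502326348847,31.151411520809546
hypothalamus,preproghrelin,42,2.6973618084895996,0.15230640826860703,1.2284002932384697,0.22552998565110852,0.6176846718152837,1.8391159146616556,0.99,16.68043657253697,0.6366914240233593,36.64004373850025
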