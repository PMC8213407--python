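((((LAFA:0.060,LAME:0.055):0.100,(LAWA:0.070,LATH:0.075):0.095):0.050,(LADA:0.080,LANO:0.085):0.120):0.080,(LAMI:0.280,(LACI:0.300,LAFE:0.350):0.040):0.060);
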