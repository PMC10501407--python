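id,ic50_uM
13a,0.3
13b,0.53
13c,0.19
13d,0.4
13e,0.39
13f,0.69
13g,0.23
13h,0.64
13i,0.6
13j,0.62
13k,0.23
13l,0.55
13m,1.07
13n,0.42
13o,0.33
13p,0.42
13q,0.5
13r,0.79
13s,0.63
13t,0.53
13u,0.34
13v,0.44
21A,0.62
21B,1.02
21C,0.53
21D,0.5
21E,0.18
21F,0.76
21G,0.45
21H,0.32
21I,0.37
21J,0.91
21K,0.55
21L,0.26
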