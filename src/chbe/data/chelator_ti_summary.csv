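metal,chelator,dg_exp,dg_sim_default,dg_sim_zero,m_o,m_n
Ca2+,EDTA,-60.8,-56.0,-41.3,-0.593,-0.177
Ca2+,NTA,-37.5,-32.7,-17.6,-0.442,-0.081
Mg2+,EDTA,-50.1,-88.1,-37.6,-1.028,-0.124
Mg2+,NTA,-30.6,-84.9,-52.5,-0.842,0.077
Y3+,EDTA,-103.2,-156.0,-81.2,-0.752,-0.058
Y3+,NTA,-65.5,-148.9,-107.1,-0.691,0.008
La3+,EDTA,-87.6,-123.3,-85.0,-0.632,-0.056
La3+,NTA,-59.1,-115.4,-86.7,-0.491,-0.028
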