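metal,c_o_default,c_n_default,c_o_chbe,c_n_chbe
Ca2+,34.4,65.9,29.2,110.6
Mg2+,52.4,100.3,12.3,126.1
Y3+,85.1,163.0,14.9,161.9
La3+,59.9,114.7,9.5,46.3
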