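G01	T:07
G02	T:07
G03	T:07
G04	T:07
G05	T:07
G06	T:06
G07	T:05
G08	T:04
G09	T:02
G10	T:02
G11	T:03
G12	T:08
G13	T:08
G14	T:09
G15	T:10
G16	T:10
G17	T:11
G18	T:12
G19	T:12
G20	T:01
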