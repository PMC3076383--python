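name	handedness	polynomial
U	achiral	1
unlink_2	n/a	-l^-1*m^-1 - l^1*m^-1
unlink_3	n/a	l^-2*m^-2 + 2*m^-2 + l^2*m^-2
3_1	R	-l^-4 - 2*l^-2 + l^-2*m^2
3_1	L	-2*l^2 + l^2*m^2 - l^4
4_1	achiral	-l^-2 - 1 + m^2 - l^2
5_1	R	2*l^-6 - l^-6*m^2 + 3*l^-4 - 4*l^-4*m^2 + l^-4*m^4
5_1	L	3*l^4 - 4*l^4*m^2 + l^4*m^4 + 2*l^6 - l^6*m^2
5_2	R	l^-6 + l^-4 - l^-4*m^2 - l^-2 + l^-2*m^2
5_2	L	-l^2 + l^2*m^2 + l^4 - l^4*m^2 + l^6
6_1	R	l^-4 + l^-2 - l^-2*m^2 + m^2 - l^2
6_1	L	-l^-2 + m^2 + l^2 - l^2*m^2 + l^4
Hopf+	n/a	l^-3*m^-1 + l^-1*m^-1 - l^-1*m^1
Hopf-	n/a	l^1*m^-1 - l^1*m^1 + l^3*m^-1
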