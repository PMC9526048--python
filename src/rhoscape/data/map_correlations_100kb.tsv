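arm	window_bp	Cold	Warm	Temp
2L	100000	0.61	0.66	0.63
2R	100000	0.50	0.48	0.48
3L	100000	0.57	0.61	0.65
3R	100000	0.55	0.54	0.53
X	100000	0.32	0.38	0.42
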