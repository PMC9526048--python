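arm	window_bp	Cold	Warm	Temp
2L	200000	0.72	0.72	0.70
2R	200000	0.52	0.47	0.52
3L	200000	0.70	0.72	0.75
3R	200000	0.62	0.61	0.60
X	200000	0.38	0.44	0.46
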