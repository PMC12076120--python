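label	numerator	denominator	printed_percent
overall	21211	165303	12.83
Omeprazole	6437	32622	19.73
Esomeprazole	8832	68047	12.98
Pantoprazole	3441	29233	11.77
Rabeprazole	291	3747	7.77
Lansoprazole	2210	31654	6.98
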