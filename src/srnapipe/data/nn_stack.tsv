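pair1	pair2	energy_kcal_mol
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-1.38
AU	UG	-0.40
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-1.41
UA	UG	-0.23
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-1.66
CG	UG	-1.38
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-2.56
GC	UG	-1.54
GU	AU	-1.65
GU	UA	-1.54
GU	CG	-2.72
GU	GC	-2.56
GU	GU	-1.86
GU	UG	-0.84
UG	AU	-0.63
UG	UA	-0.23
UG	CG	-1.65
UG	GC	-1.41
UG	GU	-0.71
UG	UG	0.00
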