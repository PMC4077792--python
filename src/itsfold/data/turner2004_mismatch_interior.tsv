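# Turner 2004 interior-loop terminal mismatch free energies at 37 C, kcal/mol
# closing pair; x = base 5' adjacent (i+1); y = base 3' adjacent (j-1); N = unknown
pair	x	y	energy
CG	N	N	0.00
CG	N	A	0.00
CG	N	C	0.00
CG	N	G	0.00
CG	N	U	0.00
CG	A	N	0.00
CG	A	A	0.00
CG	A	C	0.00
CG	A	G	-0.80
CG	A	U	0.00
CG	C	N	0.00
CG	C	A	0.00
CG	C	C	0.00
CG	C	G	0.00
CG	C	U	0.00
CG	G	N	0.00
CG	G	A	-1.00
CG	G	C	0.00
CG	G	G	-1.00
CG	G	U	0.00
CG	U	N	0.00
CG	U	A	0.00
CG	U	C	0.00
CG	U	G	0.00
CG	U	U	-0.60
GC	N	N	0.00
GC	N	A	0.00
GC	N	C	0.00
GC	N	G	0.00
GC	N	U	0.00
GC	A	N	0.00
GC	A	A	0.00
GC	A	C	0.00
GC	A	G	-0.80
GC	A	U	0.00
GC	C	N	0.00
GC	C	A	0.00
GC	C	C	0.00
GC	C	G	0.00
GC	C	U	0.00
GC	G	N	0.00
GC	G	A	-1.00
GC	G	C	0.00
GC	G	G	-1.00
GC	G	U	0.00
GC	U	N	0.00
GC	U	A	0.00
GC	U	C	0.00
GC	U	G	0.00
GC	U	U	-0.60
GU	N	N	0.70
GU	N	A	0.70
GU	N	C	0.70
GU	N	G	0.70
GU	N	U	0.70
GU	A	N	0.70
GU	A	A	0.70
GU	A	C	0.70
GU	A	G	-0.10
GU	A	U	0.70
GU	C	N	0.70
GU	C	A	0.70
GU	C	C	0.70
GU	C	G	0.70
GU	C	U	0.70
GU	G	N	0.70
GU	G	A	-0.30
GU	G	C	0.70
GU	G	G	-0.30
GU	G	U	0.70
GU	U	N	0.70
GU	U	A	0.70
GU	U	C	0.70
GU	U	G	0.70
GU	U	U	0.10
UG	N	N	0.70
UG	N	A	0.70
UG	N	C	0.70
UG	N	G	0.70
UG	N	U	0.70
UG	A	N	0.70
UG	A	A	0.70
UG	A	C	0.70
UG	A	G	-0.10
UG	A	U	0.70
UG	C	N	0.70
UG	C	A	0.70
UG	C	C	0.70
UG	C	G	0.70
UG	C	U	0.70
UG	G	N	0.70
UG	G	A	-0.30
UG	G	C	0.70
UG	G	G	-0.30
UG	G	U	0.70
UG	U	N	0.70
UG	U	A	0.70
UG	U	C	0.70
UG	U	G	0.70
UG	U	U	0.10
AU	N	N	0.70
AU	N	A	0.70
AU	N	C	0.70
AU	N	G	0.70
AU	N	U	0.70
AU	A	N	0.70
AU	A	A	0.70
AU	A	C	0.70
AU	A	G	-0.10
AU	A	U	0.70
AU	C	N	0.70
AU	C	A	0.70
AU	C	C	0.70
AU	C	G	0.70
AU	C	U	0.70
AU	G	N	0.70
AU	G	A	-0.30
AU	G	C	0.70
AU	G	G	-0.30
AU	G	U	0.70
AU	U	N	0.70
AU	U	A	0.70
AU	U	C	0.70
AU	U	G	0.70
AU	U	U	0.10
UA	N	N	0.70
UA	N	A	0.70
UA	N	C	0.70
UA	N	G	0.70
UA	N	U	0.70
UA	A	N	0.70
UA	A	A	0.70
UA	A	C	0.70
UA	A	G	-0.10
UA	A	U	0.70
UA	C	N	0.70
UA	C	A	0.70
UA	C	C	0.70
UA	C	G	0.70
UA	C	U	0.70
UA	G	N	0.70
UA	G	A	-0.30
UA	G	C	0.70
UA	G	G	-0.30
UA	G	U	0.70
UA	U	N	0.70
UA	U	A	0.70
UA	U	C	0.70
UA	U	G	0.70
UA	U	U	0.10
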