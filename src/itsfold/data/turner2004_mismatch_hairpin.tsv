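# Turner 2004 hairpin-loop terminal mismatch free energies at 37 C, kcal/mol
# closing pair; x = base 5' adjacent (i+1); y = base 3' adjacent (j-1); N = unknown
pair	x	y	energy
CG	N	N	-0.80
CG	N	A	-1.00
CG	N	C	-1.10
CG	N	G	-1.00
CG	N	U	-0.80
CG	A	N	-1.40
CG	A	A	-1.50
CG	A	C	-1.50
CG	A	G	-1.40
CG	A	U	-1.50
CG	C	N	-0.80
CG	C	A	-1.00
CG	C	C	-1.10
CG	C	G	-1.00
CG	C	U	-0.80
CG	G	N	-1.50
CG	G	A	-2.30
CG	G	C	-1.50
CG	G	G	-2.40
CG	G	U	-1.50
CG	U	N	-1.00
CG	U	A	-1.00
CG	U	C	-1.40
CG	U	G	-1.00
CG	U	U	-2.10
GC	N	N	-0.50
GC	N	A	-1.10
GC	N	C	-0.70
GC	N	G	-1.10
GC	N	U	-0.50
GC	A	N	-1.10
GC	A	A	-1.10
GC	A	C	-1.50
GC	A	G	-1.30
GC	A	U	-1.50
GC	C	N	-0.50
GC	C	A	-1.10
GC	C	C	-0.70
GC	C	G	-1.10
GC	C	U	-0.50
GC	G	N	-1.50
GC	G	A	-2.50
GC	G	C	-1.50
GC	G	G	-2.20
GC	G	U	-1.50
GC	U	N	-1.00
GC	U	A	-1.10
GC	U	C	-1.00
GC	U	G	-1.10
GC	U	U	-1.60
GU	N	N	0.20
GU	N	A	0.20
GU	N	C	-0.20
GU	N	G	-0.10
GU	N	U	-0.20
GU	A	N	0.20
GU	A	A	0.20
GU	A	C	-0.50
GU	A	G	-0.30
GU	A	U	-0.50
GU	C	N	-0.10
GU	C	A	-0.10
GU	C	C	-0.20
GU	C	G	-0.10
GU	C	U	-0.20
GU	G	N	-0.50
GU	G	A	-1.00
GU	G	C	-0.50
GU	G	G	-1.10
GU	G	U	-0.50
GU	U	N	-0.10
GU	U	A	-0.10
GU	U	C	-0.30
GU	U	G	-0.10
GU	U	U	-1.00
UG	N	N	0.00
UG	N	A	-0.20
UG	N	C	-0.10
UG	N	G	-0.20
UG	N	U	0.00
UG	A	N	-0.30
UG	A	A	-0.50
UG	A	C	-0.30
UG	A	G	-0.60
UG	A	U	-0.30
UG	C	N	0.00
UG	C	A	-0.20
UG	C	C	-0.10
UG	C	G	-0.20
UG	C	U	0.00
UG	G	N	-0.30
UG	G	A	-0.90
UG	G	C	-0.30
UG	G	G	-1.10
UG	G	U	-0.30
UG	U	N	-0.10
UG	U	A	-0.20
UG	U	C	-0.10
UG	U	G	-0.20
UG	U	U	-0.90
AU	N	N	-0.10
AU	N	A	-0.10
AU	N	C	-0.20
AU	N	G	-0.10
AU	N	U	-0.20
AU	A	N	-0.30
AU	A	A	-0.30
AU	A	C	-0.50
AU	A	G	-0.30
AU	A	U	-0.50
AU	C	N	-0.10
AU	C	A	-0.10
AU	C	C	-0.20
AU	C	G	-0.10
AU	C	U	-0.20
AU	G	N	-0.50
AU	G	A	-1.20
AU	G	C	-0.50
AU	G	G	-1.10
AU	G	U	-0.50
AU	U	N	-0.10
AU	U	A	-0.10
AU	U	C	-0.30
AU	U	G	-0.10
AU	U	U	-1.20
UA	N	N	0.00
UA	N	A	-0.20
UA	N	C	-0.10
UA	N	G	-0.20
UA	N	U	0.00
UA	A	N	-0.30
UA	A	A	-0.50
UA	A	C	-0.30
UA	A	G	-0.50
UA	A	U	-0.30
UA	C	N	0.00
UA	C	A	-0.20
UA	C	C	-0.10
UA	C	G	-0.20
UA	C	U	0.00
UA	G	N	-0.30
UA	G	A	-1.50
UA	G	C	-0.30
UA	G	G	-1.50
UA	G	U	-0.30
UA	U	N	-0.10
UA	U	A	-0.20
UA	U	C	-0.10
UA	U	G	-0.20
UA	U	U	-0.90
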