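# Turner 2004 miscellaneous free-energy parameters at 37 C, kcal/mol
# lxc: coefficient of the logarithmic long-loop extrapolation dG(n>30) = dG(30) + lxc*ln(n/30)
param	value
ml_unpaired	0.00
ml_closing	9.30
ml_branch	-0.90
ninio_m	0.60
ninio_max	3.00
terminal_au	0.50
lxc	1.07856
max_interior	30
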