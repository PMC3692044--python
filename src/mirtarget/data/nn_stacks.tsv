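# Simplified RNA nearest-neighbor parameters at 37 C, kcal/mol.
# Watson-Crick stack terms follow the Turner-2004 style of published
# nearest-neighbor tables; G:U wobble terms are a simplified set.
# stack <top1><bottom1> <top2><bottom2> dG  means the dinucleotide step
#   5'-t1 t2-3'
#   3'-b1 b2-5'
# Rotational symmetry (reading the other strand 5'->3') is applied on
# load, so only one member of each symmetry class is listed.
param	duplex_init	4.09
param	au_end_penalty	0.45
param	loop_base	3.20
param	loop_per_nt	0.40
param	ss_pair_cost	1.60
param	max_loop	30
param	min_hairpin	3
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	GC	UA	-2.24
stack	CG	UA	-2.08
stack	GC	AU	-2.35
stack	CG	AU	-2.11
stack	GC	GC	-3.26
stack	CG	GC	-2.36
stack	GC	CG	-3.42
stack	AU	GU	-0.55
stack	AU	UG	-1.36
stack	UA	GU	-1.27
stack	UA	UG	-1.00
stack	CG	GU	-1.41
stack	CG	UG	-2.11
stack	GC	GU	-1.53
stack	GC	UG	-2.51
stack	GU	GU	-0.50
stack	GU	UG	0.47
stack	UG	GU	-0.60
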