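# ACMG/AMP 2015 evidence-combining clauses.
# Minimum counts per strength bucket; a clause fires when every minimum is met.
# Pathogenic clauses are evaluated before likely-pathogenic, benign before
# likely-benign, so the guideline's upper bounds (e.g. "1 PS + 1-2 PM") fall
# out of the ordering.
clause_id	class	pvs	ps	pm	pp	ba	bs	bp
P_ia	pathogenic	1	1	0	0	0	0	0
P_ib	pathogenic	1	0	2	0	0	0	0
P_ic	pathogenic	1	0	1	1	0	0	0
P_id	pathogenic	1	0	0	2	0	0	0
P_ii	pathogenic	0	2	0	0	0	0	0
P_iiia	pathogenic	0	1	3	0	0	0	0
P_iiib	pathogenic	0	1	2	2	0	0	0
P_iiic	pathogenic	0	1	1	4	0	0	0
LP_i	likely_pathogenic	1	0	1	0	0	0	0
LP_ii	likely_pathogenic	0	1	1	0	0	0	0
LP_iii	likely_pathogenic	0	1	0	2	0	0	0
LP_iv	likely_pathogenic	0	0	3	0	0	0	0
LP_v	likely_pathogenic	0	0	2	2	0	0	0
LP_vi	likely_pathogenic	0	0	1	4	0	0	0
B_i	benign	0	0	0	0	1	0	0
B_ii	benign	0	0	0	0	0	2	0
LB_i	likely_benign	0	0	0	0	0	1	1
LB_ii	likely_benign	0	0	0	0	0	0	2
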