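# Sequencing results of a published 29-patient pediatric neurology WES cohort,
# transcribed as printed (one row per reported variant; ND = no candidate
# finding). Per-patient sex is reconstructed: the source reports only the
# 19 male / 10 female aggregate, so sexes here are chosen to respect that
# aggregate and the X-linked inheritance outcomes it reports.
patient_id	sex	gene	position	nucleotide_change	protein_change	inheritance	phenotypes
1	male	COMP	chr19:18896846	c.1418A>G	p.D473G	AD	Gait instability, worse in the dark; dystonia
2	female	DYNC1H1	chr14:102499762	c.10354G>A	p.A3452T	AD	Intellectual disability; hearing abnormity; congenital cataract; talipes equinovarus; brain atrophy
2	female	CRYBB2	chr22:25627591	c.470C>G	p.P157R	AD	Intellectual disability; hearing abnormity; congenital cataract; talipes equinovarus; brain atrophy
3	male	ADNP	chr20:49520469	c.64dupA	p.I22fs	AD	Intellectual disability; dark skin; abnormal facial shape
4	male	SYNE2	chr14:64675492	c.18218T>C	p.I6073T	AD	Global development delay; autism; optic atrophy; gait disturbance
5	female	COL6A3	chr2:238245098	c.8645C>T	p.P2882L	AD/AR	Intellectual disability; abnormal facial shape; dystonia; muscle weakness
5	female	COL6A3	chr2:238275918	c.4912G>A	p.A1638T	AD/AR	Intellectual disability; abnormal facial shape; dystonia; muscle weakness
6	male	CHD2	chr15:93498742	c.1809G>T	p.K603N	AD	Seizures; epileptic encephalopathy; intellectual disability; microcephaly
6	male	CHD2	chr15:93498743	c.1809+1G>T	Splicing	AD	Seizures; epileptic encephalopathy; intellectual disability; microcephaly
7	male	HCFC1	chrX:153220254	c.3596G>C	p.R1199P	XR	Intellectual disability; abnormal facial shape; autism
8	male	SUCLG1	chr2:84652709	c.884G>A	p.V282I	AR	Intellectual disability; short stature
8	male	SUCLG1	chr2:84660557	c.592A>G	p.I198V	AR	Intellectual disability; short stature
9	female	SMARCAL1	chr2:217285085	c.926G>A	p.S309N	AR	Seizures; Intellectual disability; microcephaly; abnormal ear morphology
9	female	SMARCAL1	chr2:217332750	c.2225C>T	p.T742M	AR	Seizures; Intellectual disability; microcephaly; abnormal ear morphology
10	male	MTHFR	chr1:11856378	c.665C>T	p.A222V	AR	Seizures; Intellectual disability; abnormality of metabolism/homeostasis
10	male	MTHFR	chr1:11863038	c.136C>T	p.R46W	AR	Seizures; Intellectual disability; abnormality of metabolism/homeostasis
11	female	CDKL5	chrX:18582616	c.119C>T	p.A40V	XD	Intellectual disability; seizures
12	female	PDGFRB	chr5:149512504	c.936G>C	p.E312D	AD	Intellectual disability; hypertonia; esotropia; abnormality of metabolism/homeostasis
13	male	TUBA1A	chr12:49579133	c.1016G>T	p.R339L	AD	Delayed gross motor development; Intellectual disability; agenesis of corpus callosum
14	female	SMC1A	chrX:53441721	c.331T>G	p.F111V	XD	Intellectual disability; cryptorchidism; Short stature
15	male	HUWE1	chrX:53578276	c.9047A>C	p.E3016A	Unknown	Intellectual disability; autism
15	male	MAPT	chr17:44060834	c.664C>G	p.R222G	AD	Intellectual disability; autism
16	female	MECP2	chrX:153296153	c.1162C>T	p.P388S	XD/XR	Intellectual disability; autism
16	female	KCNC1	chr11:17793707	c.1066G>A	p.V356M	AD	Intellectual disability; autism
17	male	DYNC1H1	chr14:102463472	c.3665A>G	p.N1222S	AD	Intellectual disability; elevated urine guanidinoacetic acid
17	male	XDH	chr2:31596756	c.1669G>A	p.D557N	AR	Intellectual disability; elevated urine guanidinoacetic acid
17	male	XDH	chr2:31598377	c.1471G>A	p.A491T	AR	Intellectual disability; elevated urine guanidinoacetic acid
18	male	IGHMBP2	chr11:68702842	c.1708C>T	p.R570X	AR	Delayed gross motor development; Intellectual disability; ulnar claw
18	male	IGHMBP2	chr11:68704545	c.2598_2599del	p.K866Sfs	AR	Delayed gross motor development; Intellectual disability; ulnar claw
19	male	CHD2	chr15:93563380	c.5045A>G	p.D1682G	AD	Seizures; global development delay; high palate
19	male	CSF1R	chr5:149433641	c.2909_2910insATCA	p.Q970fs	AD	Seizures; global development delay; high palate
19	male	EZH2	chr7:148544336	c.55G>A	p.V19I	AD	Seizures; global development delay; high palate
20	male	ND	ND	ND	ND	ND	Seizures
21	male	ND	ND	ND	ND	ND	Intellectual disability; autism
22	male	ND	ND	ND	ND	ND	Seizures; glutaric aciduria
23	male	ALDH7A1	chr5:125919644	c.454A>G	p.I152V	AR	Seizures (VB6 improvement); intellectual disability; dyspepsia
24	female	ND	ND	ND	ND	ND	Intellectual disability; microcephaly; abnormality of metabolism/homeostasis
25	male	ND	ND	ND	ND	ND	Seizures; intellectual disability; vitamin B6 deficiency
26	female	SLC22A5	chr5:131728257	c.1400C>G	p.S467C	AR	Intellectual disability; cerebellar atrophy
27	male	ND	ND	ND	ND	ND	Seizure; arachnoid cyst
28	female	ND	ND	ND	ND	ND	Intellectual disability; autism
29	male	ND	ND	ND	ND	ND	Multiple-malformation; dystonia
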