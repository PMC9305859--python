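gene	cdna_change	protein_change	variant_type	mutated_samples	previously_reported	exposure_arm
BRCA1	c.181T>G	p.C61G	SNP	2	Yes	Exposed/unexposed
BRCA1	c.3329delA	p.K1110fs	DEL	1	Yes	Exposed
BRCA1	c.3790_3797delAAGAATAG	p.K1264fs	DEL	1	No	Exposed
BRCA1	c.1687C>T	p.Q563*	SNP	1	Yes	Exposed
BRCA1	c.3765_3786delCACAGAGGAGAATTTATTATCA	p.T1256fs	DEL	1	No	Exposed
BRCA1	c.5129G>A	p.G1710E	SNP	1	Yes	Exposed
BRCA1	c.546G>T	p.L182F	SNP	1	Yes	Unexposed
BRCA1	c.1996C>G	p.L666V	SNP	1	Yes	Unexposed
BRCA2	c.2806_2809delAAAC	p.A938fs	DEL	1	Yes	Unexposed
BRCA2	c.7879A>T	p.I2627F	SNP	1	Yes	Exposed
BRCA2	c.5067delA	p.K1691fs	DEL	1	Yes	Exposed
BRCA2	c.1314delT	p.T441fs	DEL	1	Yes	Exposed
BRCA2	c.5687C>T	p.A1896V	SNP	1	Yes	Exposed
BRCA2	c.5096A>G	p.D1699G	SNP	1	Yes	Unexposed
BRCA2	c.670G>A	p.D224N	SNP	1	Yes	Unexposed
BRCA2	c.3562A>G	p.I1188V	SNP	1	Yes	Exposed
PALB2	c.1314delA	p.F440fs	DEL	1	Yes	Exposed
PALB2	c.886delA	p.M296fs	DEL	6	Yes	Exposed
PALB2	c.1240C>T	p.R414*	DEL	1	Yes	Unexposed
PALB2	c.2453T>C	p.F818S	SNP	1	Yes	Unexposed
PALB2	c.2201C>A	p.T734N	SNP	1	Yes	Unexposed
PALB2	c.2608G>A	p.V870I	SNP	1	Yes	Exposed
TP53	c.481delG	p.A161fs	DEL	1	No	Exposed
TP53	c.592G>T	p.E198*	SNP	2	Yes	Exposed
TP53	c.856G>A	p.E286K	SNP	1	Yes	Exposed
TP53	c.730G>A	p.G244S	SNP	1	Yes	Exposed
TP53	c.734G>A	p.G245D	SNP	1	Yes	Unexposed
TP53	c.578A>C	p.H193P	SNP	1	Yes	Unexposed
TP53	c.617delT	p.L206fs	DEL	1	No	Unexposed
TP53	c.736A>G	p.M246V	SNP	1	Yes	Exposed
TP53	c.454_466delCCGCCCGGCACCC	p.P152fs	DEL	1	Yes	Exposed
TP53	c.586C>T	p.R196*	SNP	1	Yes	Exposed
TP53	c.626_627delGA	p.R209fs	DEL	1	Yes	Exposed
TP53	c.637C>T	p.R213*	SNP	1	Yes	Exposed
TP53	c.742C>T	p.R248W	SNP	1	Yes	Unexposed
TP53	c.818G>A	p.R273H	SNP	1	Yes	Exposed
TP53	c.447delC	p.T150fs	DEL	1	No	Unexposed
TP53	c.517G>A	p.V173M	SNP	1	Yes	Exposed
TP53	c.796G>A	p.G266R	SNP	1	Yes	Exposed
TP53	c.535C>A	p.H179N	SNP	1	Yes	Unexposed
TP53	c.536A>G	p.H179R	SNP	1	Yes	Unexposed
TP53	c.578A>G	p.H193R	SNP	2	Yes	Exposed/unexposed
TP53	c.711G>T	p.M237I	SNP	1	Yes	Unexposed
TP53	c.832C>T	p.P278S	SNP	1	Yes	Exposed
TP53	c.614A>G	p.Y205C	SNP	1	Yes	Exposed
TP53	c.613T>C	p.Y205H	SNP	1	Yes	Unexposed
TP53	c.96+2T>CTGGT	Splice site	INS	1	No	Unexposed
TP53	c.559+1G>C	Splice site	SNP	1	No	Exposed
RAD51D	c.56T>C	p.L19P	SNP	1	Yes	Unexposed
RAD51D	c.137C>G	p.S46C	SNP	2	Yes	Exposed/unexposed
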