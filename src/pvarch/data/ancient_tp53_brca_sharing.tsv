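gene	hgvs_c	hgvs_p	consequence	african	nonafrican	earliest_bp
TP53	c.814G>A	p.Val272Met	nonsynonymous SNV	-	+	2,409
TP53	c.1010G>A	p.Arg337His	nonsynonymous SNV	-	+	2,530
TP53	c.638G>A	p.Arg213Gln	nonsynonymous SNV	-	+	2,549
TP53	c.736A>G	p.Met246Val	nonsynonymous SNV	-	+	3,328
TP53	c.542G>A	p.Arg181His	nonsynonymous SNV	-	+	4,450
TP53	c.817C>T	p.Arg273Cys	nonsynonymous SNV	-	+	4,500
TP53	c.451C>T	p.Pro151Ser	nonsynonymous SNV	-	+	4,500
TP53	c.455C>T	p.Pro152Leu	nonsynonymous SNV	-	+	4,500
TP53	c.713G>A	p.Cys238Tyr	nonsynonymous SNV	-	+	4,725
TP53	c.853G>A	p.Glu285Lys	nonsynonymous SNV	-	+	6,713
TP53	c.844C>T	p.Arg282Trp	nonsynonymous SNV	-	+	6,960
TP53	c.742C>T	p.Arg248Trp	nonsynonymous SNV	-	+	10,000
TP53	c.734G>A	p.Gly245Asp	nonsynonymous SNV	-	+	34,425
TP53	c.473G>A	p.Arg158His	nonsynonymous SNV	+	+	4,160
TP53	c.818G>A	p.Arg273His	nonsynonymous SNV	+	+	6,415
TP53	c.733G>A	p.Gly245Ser	nonsynonymous SNV	+	+	6,483
TP53	c.743G>A	p.Arg248Gln	nonsynonymous SNV	+	+	7,515
TP53	c.841G>A	p.Asp281Asn	nonsynonymous SNV	+	-	1724
TP53	c.375G>A	p.Tyr126Valfs*23	synonymous SNV	+	-	2,927
BRCA1	c.4573C>T	p.Gln1525*	stopgain	-	+	419
BRCA1	c.5497G>A	p.Val1833Met	nonsynonymous SNV	-	+	2,185
BRCA1	c.5096G>A	p.Arg1699Gln	nonsynonymous SNV	-	+	2,600
BRCA1	c.5444G>A	p.Trp 1815*	stopgain	-	+	4,079
BRCA1	c.514C>T	p.Gln172*	stopgain	-	+	4,500
BRCA1	c.962G>A	p.Trp321*	stopgain	-	+	4,500
BRCA1	c.5503C>T	p.Arg 1835*	stopgain	-	+	4,575
BRCA1	c.34C>T	p.Gln12*	stopgain	-	+	4,839
BRCA1	c.2338C>T	p.Gln780*	stopgain	-	+	5,350
BRCA1	c.3403C>T	p.Gln1135*	stopgain	-	+	6,319
BRCA1	c.4675G>A	p.Glu1559Argfs*15	nonsynonymous SNV	-	+	6,373
BRCA1	c.1687C>T	p.Gln563*	stopgain	-	+	6,483
BRCA1	c.4834C>T	p.Gln1612*	stopgain	-	+	7,200
BRCA1	c.5095C>T	p.Arg1699Trp	nonsynonymous SNV	-	+	9,872
BRCA1	c.181T>G	p.Cys61Gly	nonsynonymous SNV	-	+	37,470
BRCA1	c.4327C>T	p.Arg1443*	stopgain	+	+	4,600
BRCA1	c.3607C>T	p.Arg1203*	stopgain	+	+	6,415
BRCA1	c.5251C>T	p.Arg1751*	stopgain	+	+	NA
BRCA2	c.5992C>T	p.Gln 1998*	stopgain	-	+	450
BRCA2	c.3G>A	p.?	startloss	-	+	1964
BRCA2	c.5773C>T	p.Gln 1925*	stopgain	-	+	1964
BRCA2	c.7757G>A	p.Trp2586*	stopgain	-	+	3,000
BRCA2	c.8377G>A	p.Gly2793Arg	nonsynonymous SNV	-	+	3,070
BRCA2	c.8754G>A	p.=	synonymous SNV	-	+	3,532
BRCA2	c.9117G>A	p.=	synonymous SNV	-	+	4,225
BRCA2	c.2224C>T	p.Gln742*	stopgain	-	+	4,239
BRCA2	c.7615C>T	p.Gln2539*	stopgain	-	+	4,450
BRCA2	c.9154C>T	p.Arg3052Trp	nonsynonymous SNV	-	+	4,800
BRCA2	c.7480C>T	p.Arg2494*	stopgain	-	+	6,319
BRCA2	c.6952C>T	p.Arg2318*	stopgain	-	+	7,515
BRCA2	c.772C>T	p.Gln258*	stopgain	-	+	10,000
BRCA2	c.7878G>A	p.Trp2626*	stopgain	-	+	10,000
BRCA2	c.92G>A	p.Trp31*	stopgain	-	+	31,630
BRCA2	c.8009C>T	p.Ser2670Leu	nonsynonymous SNV	+	+	400
BRCA2	c.9294C>G	p.Tyr3098*	stopgain	+	+	2,221
BRCA2	c.7558C>T	p.Arg2520*	stopgain	+	+	2,305
BRCA2	c.9382C>T	p.Arg3128*	stopgain	+	+	8,610
BRCA2	c.7115C>G	p.Ser2372*	stopgain	+	-	1,595
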