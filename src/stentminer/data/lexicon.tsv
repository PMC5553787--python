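term	kind	category	device_class	generation	polymer
LAD	vessel	LAD	-	-	-
Di	vessel	LAD	-	-	-
D1	vessel	LAD	-	-	-
D2	vessel	LAD	-	-	-
diagonal	vessel	LAD	-	-	-
Dx	vessel	LAD	-	-	-
LCx	vessel	LCx	-	-	-
OM	vessel	LCx	-	-	-
RI	vessel	LCx	-	-	-
Ramus	vessel	LCx	-	-	-
LM	vessel	LM	-	-	-
LM-LAD	vessel	LM	-	-	-
LM-LCx	vessel	LM	-	-	-
RCA	vessel	RCA	-	-	-
PDA	vessel	RCA	-	-	-
PLV	vessel	RCA	-	-	-
PLB	vessel	RCA	-	-	-
Vision	stent	Vision	BMS	none	none
Multi-Link Vision	stent	Vision	BMS	none	none
ML Vision	stent	Vision	BMS	none	none
Genoss	stent	Genoss	BMS	none	none
Coroflex Blue	stent	Coroflex Blue	BMS	none	none
Zeta	stent	Zeta	BMS	none	none
Cypher	stent	Cypher	DES	first	none
Cypher Select	stent	Cypher	DES	first	none
Coroflex Please	stent	Coroflex Please	DES	first	none
Taxus	stent	Taxus	DES	first	none
Taxus Liberte	stent	Taxus	DES	first	none
Taxus Express	stent	Taxus	DES	first	none
Resolute	stent	Resolute	DES	second	durable
Resolute Integrity	stent	Resolute	DES	second	durable
Resolute Onyx	stent	Resolute	DES	second	durable
Promus	stent	Promus	DES	second	durable
Promus Element	stent	Promus	DES	second	durable
Promus Premier	stent	Promus	DES	second	durable
Xience	stent	Xience	DES	second	durable
Xience V	stent	Xience	DES	second	durable
Xience Prime	stent	Xience	DES	second	durable
Xience Xpedition	stent	Xience	DES	second	durable
Xience Alpine	stent	Xience	DES	second	durable
Endeavor	stent	Endeavor	DES	second	durable
Endeavor Sprint	stent	Endeavor	DES	second	durable
Biomatrix	stent	Biomatrix	DES	second	biodegradable
Biomatrix Flex	stent	Biomatrix	DES	second	biodegradable
Desyne	stent	Desyne	DES	second	biodegradable
Nobori	stent	Nobori	DES	second	biodegradable
Orsiro	stent	Orsiro	DES	second	biodegradable
NC Quantum	balloon	-	-	-	-
NC Quantum Apex	balloon	-	-	-	-
NC Sprinter	balloon	-	-	-	-
NC Trek	balloon	-	-	-	-
NC Euphora	balloon	-	-	-	-
Pantera Leo	balloon	-	-	-	-
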