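drug	drug_class
aspirin	aspirin
astrix	aspirin
p2y12	p2y12
clopidogrel	p2y12
plavix	p2y12
ticagrelor	p2y12
prasugrel	p2y12
antihypertensive	antihypertensive
amlodipine	antihypertensive
losartan	antihypertensive
valsartan	antihypertensive
telmisartan	antihypertensive
atenolol	antihypertensive
carvedilol	antihypertensive
hydrochlorothiazide	antihypertensive
antidiabetic	antidiabetic
metformin	antidiabetic
glimepiride	antidiabetic
sitagliptin	antidiabetic
insulin	antidiabetic
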