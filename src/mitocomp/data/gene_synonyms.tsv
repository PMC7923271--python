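# Synonym table mapping annotation labels to the standard 37-gene vocabulary.
# Matching is case-insensitive after stripping spaces, hyphens and underscores.
# Columns: synonym <TAB> token.  Extend freely: annotation vocabularies vary
# widely across GenBank records and annotation pipelines.
synonym	token
cox1	cox1
coi	cox1
co1	cox1
coxi	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
cytochromeoxidasesubunit1	cox1
cox2	cox2
coii	cox2
co2	cox2
coxii	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
cytochromeoxidasesubunit2	cox2
cox3	cox3
coiii	cox3
co3	cox3
coxiii	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
cytochromeoxidasesubunit3	cox3
cob	cob
cytb	cob
cytochromeb	cob
nad1	nad1
nd1	nad1
nadhdehydrogenasesubunit1	nad1
nad2	nad2
nd2	nad2
nadhdehydrogenasesubunit2	nad2
nad3	nad3
nd3	nad3
nadhdehydrogenasesubunit3	nad3
nad4	nad4
nd4	nad4
nadhdehydrogenasesubunit4	nad4
nad4l	nad4L
nd4l	nad4L
nadhdehydrogenasesubunit4l	nad4L
nad5	nad5
nd5	nad5
nadhdehydrogenasesubunit5	nad5
nad6	nad6
nd6	nad6
nadhdehydrogenasesubunit6	nad6
atp6	atp6
atpase6	atp6
atpsynthasef0subunit6	atp6
atp8	atp8
atpase8	atp8
atpsynthasef0subunit8	atp8
rrns	rrnS
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
srrna	rrnS
smallsubunitribosomalrna	rrnS
rrn12	rrnS
rrnl	rrnL
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
lrrna	rrnL
largesubunitribosomalrna	rrnL
rrn16	rrnL
trna	trnA
trnaala	trnA
trnaa	trnA
trnc	trnC
trnacys	trnC
trnac	trnC
trnd	trnD
trnaasp	trnD
trnad	trnD
trne	trnE
trnaglu	trnE
trnae	trnE
trnf	trnF
trnaphe	trnF
trnaf	trnF
trng	trnG
trnagly	trnG
trnag	trnG
trnh	trnH
trnahis	trnH
trnah	trnH
trni	trnI
trnaile	trnI
trnai	trnI
trnk	trnK
trnalys	trnK
trnak	trnK
trnl1	trnL1
trnaleucun	trnL1
trnaleu1	trnL1
trnleucun	trnL1
trnl2	trnL2
trnaleuuur	trnL2
trnaleu2	trnL2
trnleuuur	trnL2
trnm	trnM
trnamet	trnM
trnam	trnM
trnn	trnN
trnaasn	trnN
trnan	trnN
trnp	trnP
trnapro	trnP
trnap	trnP
trnq	trnQ
trnagln	trnQ
trnaq	trnQ
trnr	trnR
trnaarg	trnR
trnar	trnR
trns1	trnS1
trnaseragn	trnS1
trnaser1	trnS1
trnseragn	trnS1
trns2	trnS2
trnaserucn	trnS2
trnaser2	trnS2
trnserucn	trnS2
trnt	trnT
trnathr	trnT
trnat	trnT
trnv	trnV
trnaval	trnV
trnav	trnV
trnw	trnW
trnatrp	trnW
trnaw	trnW
trny	trnY
trnatyr	trnY
trnay	trnY
cr	CR1
cr1	CR1
cr2	CR2
controlregion	CR1
dloop	CR1
putativecontrolregion	CR1
atrichregion	CR1
noncodingregion	CR1
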