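gene_id	annotation	log2fc
BLGT_RS00625	Hsp20/alpha crystalline family protein	5,10
BLGT_RS00855	Hypothetical protein	2,18
BLGT_RS01135	PEGA domain-containing protein	2,37
BLGT_RS01265	Uridylyltransferase	2,02
BLGT_RS01310	Sugar ABC transporter substrate-binding protein	2,20
BLGT_RS02915	ABC transporter substrate-binding protein	2,04
BLGT_RS02940	LacI family DNA-binding transcriptional regulator	2,32
BLGT_RS02975	Sugar ABC transporter substrate-binding protein	2,87
BLGT_RS03150	LamB/YcsF family protein	2,13
BLGT_RS03250	Zinc ABC transporter solute-binding protein	3,19
BLGT_RS03890	CarD family transcriptional regulator	−2,18
BLGT_RS04345	YccF domain-containing protein	−2,15
BLGT_RS04350	Hypothetical protein	−2,17
BLGT_RS04520	DUF4418 family protein	−2,24
BLGT_RS04525	ABC transporter permease	−2,12
BLGT_RS07100	SPFH domain-containing protein	2,02
BLGT_RS07650	DedA family protein	−2,02
BLGT_RS07990	AmmeMemoRadiSam system protein B	2,03
BLGT_RS08190	Sugar ABC transporter substrate-binding protein	2,10
BLGT_RS08205	ROK family glucokinase	−2,08
BLGT_RS08485	Sugar ABC transporter permease	2,04
BLGT_RS08615	Circularly permuted type 2 ATP-grasp protein	2,78
BLGT_RS08920	tRNA-Met	−2,11
BLGT_RS09910	Signal recognition particle sRNA small type	2,16
BLGT_RS09925	Hypothetical protein	−2,25
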