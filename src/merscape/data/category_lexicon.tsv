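category	keyword	priority
MRG:mercury	mercur	10
MRG:czc	cobalt-zinc-cadmium	9
MRG:czc	czc	9
MRG:copper	copper	8
MRG:silver	silver	8
MRG:chromate	chromate	8
MRG:arsenic	arsenic	8
MRG:arsenic	arsenate	8
ARG	beta-lactamase	10
ARG	aminoglycoside	10
ARG	fluoroquinolone	10
ARG	phosphomycin	10
ARG	macrolide efflux	10
MGE:phage	phage	7
MGE:phage	capsid	7
MGE:phage	tail fiber	7
MGE:phage	terminase	7
MGE:phage	portal protein	7
MGE:insertion	transposase	6
MGE:insertion	transposition	6
MGE:insertion	insertion sequence	6
MGE:insertion	integrase	6
MGE:insertion	recombinase	6
MGE:plasmid	plasmid	5
MGE:plasmid	conjugative transfer	5
MGE:plasmid	replication initiator	5
MGE:plasmid	mobilization	5
MGE:plasmid	relaxase	5
MGE:plasmid	incq	5
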