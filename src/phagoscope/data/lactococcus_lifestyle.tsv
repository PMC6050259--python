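phage_pattern	lifestyle	provenance
c2	lytic	c2 group, strictly virulent lactococcal phages (dairy-associated)
bIL67	lytic	c2 group, strictly virulent
936	lytic	936 group, strictly virulent lactococcal phages (dairy-associated)
sk1	lytic	936 group, strictly virulent
jj50	lytic	936 group, strictly virulent
phi7	lytic	936 group, strictly virulent
CB13	lytic	936 group, strictly virulent
bIL170	lytic	936 group, strictly virulent
P008	lytic	936 group, strictly virulent
645	lytic	936 group, strictly virulent
P335	temperate	P335 group, contains temperate lactococcal phages
TP901	temperate	P335 group, temperate
Tuc2009	temperate	P335 group, temperate
ul36	temperate	P335 group, temperate
r1t	temperate	P335-related temperate lactococcal phage
BK5-T	temperate	P335-related temperate lactococcal phage
bIL285	temperate	bIL285-like prophage of Lactococcus lactis IL1403
bIL286	temperate	bIL285-like prophage of Lactococcus lactis IL1403
bIL309	temperate	bIL285-like prophage of Lactococcus lactis IL1403
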