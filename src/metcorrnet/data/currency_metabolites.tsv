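name	synonyms	kegg_id
ATP	adenosine triphosphate;adenosine 5'-triphosphate	C00002
ADP	adenosine diphosphate;adenosine 5'-diphosphate	C00008
AMP	adenosine monophosphate;adenosine 5'-monophosphate	C00020
NAD	NAD+;nicotinamide adenine dinucleotide	C00003
NADH	nadh	C00004
NADP	NADP+;nicotinamide adenine dinucleotide phosphate	C00006
NADPH	nadph	C00005
CoA	coenzyme A;coenzyme-A	C00010
UTP	uridine triphosphate;uridine 5'-triphosphate	C00075
UDP	uridine diphosphate;uridine 5'-diphosphate	C00015
UMP	uridine monophosphate;uridine 5'-monophosphate	C00105
GTP	guanosine triphosphate;guanosine 5'-triphosphate	C00044
GDP	guanosine diphosphate;guanosine 5'-diphosphate	C00035
H2O	water;h2o	C00001
CO2	carbon dioxide;co2	C00011
O2	oxygen;dioxygen;o2	C00007
orthophosphate	phosphate;Pi;inorganic phosphate	C00009
hydrogen	H+;proton;hydrogen ion	C00080
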