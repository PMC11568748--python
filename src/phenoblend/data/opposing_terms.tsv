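# Starter registry of antagonistic (opposing) phenotype term pairs.
# Two tab-separated HPO identifiers per line; the pair is unordered.
# Extend freely: there is no official machine-readable "opposite-of" file,
# so this list is meant to be curated per analysis.
HP:0000252	HP:0000256	# microcephaly / macrocephaly
HP:0000316	HP:0000601	# hypertelorism / hypotelorism
HP:0000347	HP:0000303	# micrognathia / mandibular prognathia
HP:0004322	HP:0000098	# short stature / tall stature
HP:0001276	HP:0001252	# hypertonia / hypotonia
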