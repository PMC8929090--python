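# Expected gel presence/absence of each primer pair across the five species.
# positives lists the species labels with a band; ambiguous=yes marks rows the
# source reports inconsistently (SD1/SD2), recorded here per its discussion text.
pair	positives	ambiguous
SL	S_indica_L;S_indica_tsusimensis	no
SP	S_pekinensis_transitra	no
ST1	S_indica_tsusimensis	no
ST2	S_indica_tsusimensis	no
SD1	S_barbata	yes
SD2	S_indica_L;S_pekinensis_transitra;S_indica_tsusimensis;S_barbata;S_baicalensis	yes
SB	S_baicalensis	no
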