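# Hox gene presence(1)/absence(0)/unknown(?) matrix over the 43-gene sarcopterygian universe,
# transcribed from the survey results and prior genome reports they cite:
# turtles, crocodiles, birds and placental mammals share the 39-gene core; lungfish and
# coelacanth retain A14/B10/C1/C3 (lungfish lacks D12, coelacanth lacks D13); caecilians keep
# C1+C3 but lack D12+B13; salamanders keep C3 (and B13) but lack D12; frogs keep C3 but lack
# B13+D12; snakes keep C3 but lack D12; lizards keep C3. HoxC3 state in marsupials and
# monotremes is unknown (flanking genomic sequence missing).
taxon	A1	A2	A3	A4	A5	A6	A7	A9	A10	A11	A13	A14	B1	B2	B3	B4	B5	B6	B7	B8	B9	B10	B13	C1	C3	C4	C5	C6	C8	C9	C10	C11	C12	C13	D1	D3	D4	D8	D9	D10	D11	D12	D13
coelacanth	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0
lungfish	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
caecilian	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
salamander	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
frog	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
snake	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
lizard	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
turtle	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
crocodile	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
bird	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
placental	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
marsupial	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	?	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
monotreme	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	1	0	?	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
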