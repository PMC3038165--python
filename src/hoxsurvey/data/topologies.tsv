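# Named rooted topologies used for gene-content parsimony analyses.
# hypothesis_A..D: the four classical placements of turtles among living amniotes
#   A: turtles sister to all other (diapsid) reptiles; B: turtles sister to lepidosaurs;
#   C: turtles sister to archosaurs; D: turtles inside archosaurs, sister to crocodiles.
# accepted: the working sarcopterygian tree (Batrachia amphibians; turtle-archosaur amniotes).
# batrachia / caecilian_salamander: alternative amphibian arrangements for the HoxC1 argument.
name	newick
hypothesis_A	(mammal,(turtle,(squamate,(bird,crocodile))));
hypothesis_B	(mammal,((turtle,squamate),(bird,crocodile)));
hypothesis_C	(mammal,(squamate,(turtle,(bird,crocodile))));
hypothesis_D	(mammal,(squamate,((turtle,crocodile),bird)));
accepted	(coelacanth,(lungfish,((caecilian,(frog,salamander)),((monotreme,(marsupial,placental)),((lizard,snake),(turtle,(bird,crocodile)))))));
batrachia	(lungfish,(((frog,salamander),caecilian),amniote));
caecilian_salamander	(lungfish,(((salamander,caecilian),frog),amniote));
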