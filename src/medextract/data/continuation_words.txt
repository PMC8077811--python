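# French prepositions and coordinating conjunctions that block a sentence
# boundary when adjacent to a period or line break.
# coordinating conjunctions
mais
ou
et
donc
or
ni
car
# prepositions
a
apres
avant
avec
chez
contre
dans
de
depuis
derriere
des
devant
durant
en
entre
envers
hors
jusque
jusqu
malgre
par
parmi
pendant
pour
pres
sans
selon
sous
suivant
sur
vers
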