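# English words that collide with disease synonyms.  A synonym equal to one
# of these (case-insensitive) is dropped from the disease dictionary surface
# forms; the canonical disease name is always retained.
stroke
growth
depression
shock
fits
consumption
thrush
presentation
gas
attack
cold
corns
stones
cataract
canker
palsy
grip
grippe
pica
mole
wart
tic
sty
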