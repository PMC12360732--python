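phrase,category,subcategory
hookup,sex_related,partner_seeking
hook up,sex_related,partner_seeking
dtf,sex_related,partner_seeking
fwb,sex_related,partner_seeking
netflix and chill,sex_related,partner_seeking
looking for fun,sex_related,partner_seeking
nsa fun,sex_related,partner_seeking
raw,sex_related,condomless
bareback,sex_related,condomless
bb,sex_related,condomless
no condom,sex_related,condomless
prep,sex_related,prevention
poz,sex_related,status
neg,sex_related,status
ddf,sex_related,status
party and play,drug_related,party
pnp,drug_related,party
parti,drug_related,party
tina,drug_related,stimulant
meth,drug_related,stimulant
crystal,drug_related,stimulant
ice,drug_related,stimulant
spun,drug_related,stimulant
molly,drug_related,club
poppers,drug_related,club
g,drug_related,club
blow,drug_related,stimulant
slam,drug_related,injection
slamming,drug_related,injection
point,drug_related,injection
rig,drug_related,injection
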