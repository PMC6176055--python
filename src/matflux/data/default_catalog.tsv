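# Default marker-gene catalog for carbon/nitrogen cycling and phototrophy
# in thermal microbial mats. One row per marker gene; a symbol may indicate
# exactly one pathway. hzsA (anammox) is included even where surveys find it
# absent: zero-count pathways are reported as zeros, not dropped.
symbol	pathway_id	pathway_name	process_class
psaA	oxygenic_photosynthesis	Oxygenic photosynthesis (PSI/PSII)	oxygenic_photosynthesis
psbA	oxygenic_photosynthesis	Oxygenic photosynthesis (PSI/PSII)	oxygenic_photosynthesis
pscA	anoxygenic_phototrophy	Anoxygenic phototrophy (RC1/RC2)	anoxygenic_phototrophy
pufM	anoxygenic_phototrophy	Anoxygenic phototrophy (RC1/RC2)	anoxygenic_phototrophy
fmoA	anoxygenic_phototrophy	Anoxygenic phototrophy (RC1/RC2)	anoxygenic_phototrophy
bchC	anoxygenic_phototrophy	Anoxygenic phototrophy (RC1/RC2)	anoxygenic_phototrophy
rbcL	cbb_cycle	Calvin-Benson-Bassham cycle	carbon_fixation
mcl	hp_bicycle	3-hydroxypropionate bi-cycle	carbon_fixation
mcr	hp_bicycle	3-hydroxypropionate bi-cycle	carbon_fixation
prpE	hp_bicycle	3-hydroxypropionate bi-cycle	carbon_fixation
atoB	hh_cycle	Hydroxypropionate-hydroxybutyrate cycle	carbon_fixation
crt	hh_cycle	Hydroxypropionate-hydroxybutyrate cycle	carbon_fixation
abfD	hh_cycle	Hydroxypropionate-hydroxybutyrate cycle	carbon_fixation
sucD	hh_cycle	Hydroxypropionate-hydroxybutyrate cycle	carbon_fixation
nifH	n2_fixation	Nitrogen fixation	nitrogen_cycle
glnA	ammonia_assimilation	Ammonia assimilation	nitrogen_cycle
amt	ammonia_assimilation	Ammonia assimilation	nitrogen_cycle
amoA	ammonia_oxidation	Ammonia oxidation	nitrogen_cycle
nrfA	dnra	Dissimilatory nitrate reduction to ammonium	nitrogen_cycle
nosZ	denitrification	Denitrification	nitrogen_cycle
hzsA	anammox	Anaerobic ammonium oxidation	nitrogen_cycle
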