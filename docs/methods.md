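# Methods

## Tracer uptake model

The dissolved-pool enrichment is the standard two-component isotope mixing
identity. Mixing `V_add` litres of tracer at concentration `T_conc` and
atom fraction `f_t` into an incubation of volume `V_inc` containing the
substrate at ambient concentration `Nat_conc` and natural abundance
`Nat_ab` (atom %) gives heavy moles `V_add·T_conc·f_t +
V_inc·Nat_conc·Nat_ab/100` out of total moles `V_add·T_conc +
V_inc·Nat_conc`; the excess enrichment `%R_exc` is that atom % minus
`Nat_ab`. The implementation divides through by `V_inc` (working with the
added-tracer concentration `A = V_add·T_conc/V_inc`), which is why every
consistent unit system — SI, or mL with µmol L⁻¹ — gives identical
results; the unit-invariance property is asserted in the tests, and the
test suite carries an independent mole-bookkeeping oracle (explicit
heavy/total mole accounting, no shared code) against which the
implementation agrees to better than 1e-9 relative over randomized
parameter sweeps including tracer purities of 0.98–1.0. `f_t` is exposed
because commercial tracers are typically 98–99 atom %; `f_t = 1`
reproduces the idealized pure-tracer form.

The assimilation rate divides the particulate isotopic excess
`AT_f − Nat_ab` by `%R_exc` (the fraction of newly assimilated substrate
that is labelled), scales by particulate organic N or C converted to
nanomoles (molar masses 14.0067 and 12.011 g mol⁻¹ — the mass-to-mole
handling is explicit here because the rate formula's `[PON or POC]/mg`
bookkeeping is conventionally left implicit), divides by the analyzed mat
dry mass and the incubation time, and reports nmol mg⁻¹ h⁻¹.

### Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| natural abundance ¹⁵N / ¹³C | atom % | 0.3663 / 1.108 | international standards (air N₂, VPDB); overridden by un-amended controls when present |
| tracer purity `f_t` | atom fraction | 1.0 | idealized; set 0.98–0.99 for real tracers |
| DIC pool (bicarbonate runs) | mol L⁻¹ | 8e-4 | fixed dissolved-inorganic-carbon value typical of neutral hot-spring water; overridable per row |
| detection threshold | atom % excess | 1e-3 | typical IRMS precision; at or below it the rate is 0 with `below_detection` set |
| core diameter | cm | 0.7 | the 7 mm cork-borer core; area = π(d/2)² |
| photoperiod | h d⁻¹ | 24 | daily extrapolation = hourly rate × photoperiod; whether light-dependent rates should use 24 h or daylight-only is a study-design choice, so it is a parameter, not a constant |

### Numerical choices and degenerate inputs

* Negative isotopic excess (final atom % below natural abundance) is
  measurement noise, not negative uptake: the rate clamps to 0 with a
  flag, and the raw signed value is kept in `rho_mass_raw` for
  diagnostics.
* A zero uptake rate gives an *infinite* turnover time (`math.inf`), not
  an exception; an empty dissolved pool (no ambient substrate and no
  spike) raises, because the enrichment is genuinely undefined.
* Replicate summaries use the arithmetic mean and sample SD (ddof = 1);
  a single replicate reports SD 0.
* When controls are supplied, their mean atom % replaces the default
  natural abundance *before* any replicate's rate is computed, so the
  whole chain (excess, enrichment and rate) is consistent with the
  measured baseline.

A known tension in published field protocols: tracer additions are often
described as "close to 10 % of natural abundance", yet printed spike
volumes and concentrations can imply near-total pool replacement (the
50 µL ammonium spike here enriches the 0.04 µmol L⁻¹ pool to ~99.5 %).
The pipeline follows the printed volumes and reports the computed
enrichment rather than guessing intent; users can see the discrepancy
directly in `R_exc_pct`.

## Marker-gene quantification

Normalization is FPKM — fragments per kilobase of gene length per million
library reads — the only normalization appropriate for comparing genes of
different lengths within descriptive marker surveys. The count matrix
holds only marker features, a small subset of the library, so library
sizes (total high-quality non-rRNA reads) come from the sample sheet and
are never recomputed from the matrix. A raw-count mode exists for
sensitivity analysis, since percent-of-total figures are sometimes
computed either way in the literature.

Percent-of-total for a gene is computed across a user-selected sample set
(the CLI defaults to all cDNA samples jointly, matching the convention of
normalizing day/night × temperature panels together); per-temperature
normalization is a matter of passing a different sample subset. Taxon
contributions default to genus rank with a phylum roll-up; taxa below
`min_share` (default 1 %, the conventional "less than 1 % each" reporting
cut) pool into "Other", and lineages that do not resolve to the requested
rank report as "Unclassified". All percent vectors close to 100 within
1e-9 or are explicitly zero-flagged; closure, permutation invariance and
count-rescaling invariance are property-tested.

Symbol matching is case-insensitive throughout (annotation pipelines
disagree on `pufM` vs `PufM`), and a catalog rejects duplicate symbols
even across casings. The default catalog ships 21 marker genes over 11
pathways; it includes *hzsA* (anammox) although many mat metagenomes lack
it — a zero-count pathway is reported as zero activity, never dropped,
because marker absence is itself a result.

## Synthetic data: what it emulates, what it does not

`simulate_incubation` runs the observation model forward: the spike fixes
`%R_exc`, the true rate fixes the noise-free final atom %, Gaussian noise
(SD in atom %, clipped to [0, 100]; at realistic noise scales the bounds
never bind) is added per replicate, and two un-amended controls are
emitted at natural abundance. Noise enters only through the atom %
readout: masses, volumes and times are exact, because IRMS is the step
with instrument error and no error model for the other quantities is
established. Zero-noise simulation composed with the estimator is the
identity to floating-point precision — that algebraic round trip is the
backbone of the rate tests.

`simulate_counts` draws one feature per (taxon, marker gene), gene lengths
log-uniform on [600, 3000] bp (so FPKM normalization is consequential: raw
count shares and FPKM shares genuinely differ), expected counts
proportional to taxon level × pathway weight × length, scaled to the
requested per-sample depth, then Poisson-sampled; an optional Gamma-Poisson
dispersion parameter is exposed because real libraries are overdispersed,
but the default is pure Poisson. DNA-library samples draw from taxon
*abundance* levels and cDNA samples from *activity* levels, which is what
makes abundance/transcription decoupling representable. The generator
returns exact generating share vectors for assertions; each sample's
`library_size` is the realized marker-read sum, so FPKM denominators are
self-consistent (in real data library size would be the much larger total
library, which scales all FPKM values per sample but cancels from every
share, percent and ordering the package reports).

The bundled community preset is synthetic and labelled as such: a
cyanobacterium dominant in the cool daytime community, filamentous
anoxygenic phototrophs dominant at the hot end, night-elevated
heterotrophic Proteobacteria, minor ammonia-oxidizing Thaumarchaeota, and
a silent anammox Planctomycete. Only its orderings are meaningful; the
magnitudes are invented. Consequently, passing tests demonstrate that the
estimators recover what the generative model encodes — they do not
validate read mapping, assembly, annotation or LCA assignment, which
happen upstream of this package's inputs, and they cannot certify
behaviour under real-library artifacts (contaminant reads, chimeric
contigs, mapping bias) that the generator does not model.

### Simulation sizes

Property checks run at 200 simulations per noise scenario with replicate
counts 3/12/48, community recovery at 10⁵–10⁶ reads per sample with 50
seeded repetitions — sizes at which binomial standard errors are small
relative to the generating structure while the full suite stays
interactive (a few seconds).

## Design choices that were genuinely open

* **Rate recovery without controls in the noise studies.** Simulated
  controls carry the same atom-% noise as treatments; using them to
  re-estimate an already-known natural abundance injects an
  n-independent variance floor into recovered rates. The noise-scaling
  analyses therefore recover rates against the known natural abundance,
  which makes the estimator exactly linear in the readings and the
  replicate-mean SD scale as 1/√n. Both paths are public API.
* **Whole-core vs analyzed mass.** The per-mass rate uses the dry mass
  analyzed on the IRMS; areal extrapolation takes a separately supplied
  core dry mass (defaulting to the same value) so subsampled cores are
  handled without ambiguity.
* **Catalog as a file, not a constant.** Pathway indicator sets evolve
  (additional CO₂-fixation pathways, accessory genes); the default is
  packaged data in the same TSV dialect users extend.

## Known limitations

* No isotope fractionation corrections, and no gas-phase equilibration
  model for ¹⁵N₂ bubble additions (N₂-fixation incubations need a
  dedicated protocol).
* No differential-expression statistics: outputs are descriptive
  normalized abundances, shares and ratios.
* Upstream mapping identity thresholds and assembly choices shape the
  input counts and are outside this package's scope.
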