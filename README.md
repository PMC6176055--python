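# matflux

Quantitative toolkit for hot-spring microbial-mat activity studies that
combine **stable-isotope tracer incubations** (¹⁵N/¹³C assimilation rates)
with **metagenome/metatranscriptome marker-gene profiling**. It is aimed at
biogeochemists and microbial ecologists who have (a) IRMS atom-% readouts
from spiked mat-core incubations and (b) annotated gene count tables from
shotgun DNA/cDNA libraries, and who want uptake rates, turnover times,
pathway transcription profiles and per-taxon contributions from one
consistent, tested pipeline.

## The model

**Isotope rates.** Spiking an incubation with a heavy-isotope substrate
enriches the dissolved pool to an excess enrichment

```
A      = V_add · T_conc / V_inc                      (added tracer, mol L⁻¹)
%R_exc = 100 · (A·f_t + Nat_conc · Nat_ab/100) / (Nat_conc + A) − Nat_ab
```

where `f_t` is the tracer's isotopic purity (atom fraction). After
incubating for `t_inc` hours, the particulate fraction's final atom %
(`AT_f`) gives the assimilation rate per unit dry mass

```
ρ = [(AT_f − Nat_ab) / %R_exc] · n_POM / m_dry / t_inc    (nmol mg⁻¹ h⁻¹)
```

with `n_POM` the particulate organic N or C in nmol. Rates extrapolate to
daily areal units via the core cross-section and a configurable
photoperiod, and pool turnover time is ambient concentration over
volumetric uptake. Un-amended control vials override the default natural
abundances (¹⁵N 0.3663, ¹³C 1.108 atom %); negative isotopic excess is
reported as zero with a below-detection flag.

**Marker-gene profiles.** Pathway transcription is quantified through
indicator genes (*psaA*/*psbA* for oxygenic photosynthesis, *pufM*, *pscA*,
*fmoA*, *bchC* for anoxygenic phototrophy, *rbcL* for the CBB cycle, *mcl*,
*mcr*, *prpE* for the 3-HP bi-cycle, *atoB*, *crt*, *abfD*, *sucD* for the
HH cycle, and *nifH*, *glnA*, *amt*, *amoA*, *nrfA*, *nosZ*, *hzsA* across
the nitrogen cycle — 21 markers over 11 pathways, user-extensible). Counts
are FPKM-normalized (`count / (length/10³) / (library_size/10⁶)`), summed
per pathway, expressed as percent-of-total per gene across samples, and
split into per-taxon contribution shares at phylum or genus rank. Pathways
whose markers are absent report zero — absence of a marker (e.g. *hzsA*,
hydrazine synthase) is a finding, not missing data.

A synthetic-data module generates both kinds of input with known ground
truth (forward tracer observation model; Poisson count tables with
log-uniform gene lengths), so the entire pipeline is testable end to end.

## Worked example

```python
from matflux import TracerAddition, IncubationMeasurement, CoreGeometry, compute_rate

spike = TracerAddition(v_add=50e-6, t_conc=500e-6)   # 50 uL of 500 umol/L 15NH4Cl
vial = IncubationMeasurement(
    v_inc=1e-3, nat_conc=0.04e-6, nat_abundance=0.3663,
    at_f=5.0, pom_mass_mg=0.014, mat_dry_mass_mg=10.0,
    time_inc_h=6.0, element="N", substrate="ammonium",
)
res = compute_rate(spike, vial, CoreGeometry(diameter_cm=0.7, photoperiod_hours=24))
print(f"pool enrichment  %R_exc = {res.r_exc:.2f} %")
print(f"uptake rate      rho    = {res.rho_mass:.4f} nmol N mg^-1 h^-1")
print(f"daily areal rate        = {res.rho_areal_daily:.1f} nmol N cm^-2 d^-1")
print(f"ammonium turnover       = {res.turnover_hours:.3f} h")
```

prints

```
pool enrichment  %R_exc = 99.47 %
uptake rate      rho    = 0.7760 nmol N mg^-1 h^-1
daily areal rate        = 483.9 nmol N cm^-2 d^-1
ammonium turnover       = 0.005 h
```

The spike drives the tiny ambient ammonium pool (0.04 µmol L⁻¹) to 99.5 %
enrichment; a final particulate reading of 5 atom % over 6 h then implies
0.78 nmol N per mg dry mat per hour, or ~484 nmol N cm⁻² d⁻¹ over a 7 mm
core — and at that uptake the standing ammonium pool would turn over in
fractions of an hour.

The same flow is available from the shell:

```sh
matflux simulate --out demo/sim --seed 42             # synthetic inputs + truth
matflux rates    --input demo/sim/incubation.tsv --out demo/rates
matflux quant    --annotations demo/sim/annotations.tsv \
                 --counts demo/sim/counts.tsv \
                 --samples demo/sim/samples.tsv \
                 --out demo/quant --rank phylum
matflux report   --rates demo/rates/rates_summary.tsv \
                 --activity demo/quant/pathway_activity.tsv \
                 --samples demo/sim/samples.tsv --out demo/report
```

All outputs are plain TSV with a version/config-hash header; identical
inputs and seeds give byte-identical files.

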