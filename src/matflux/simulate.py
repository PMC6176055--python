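"""Synthetic incubations and count tables with known ground truth.

Every downstream stage of the pipeline is testable without field data:

* :func:`simulate_incubation` runs the tracer observation model forward —
  given a true per-mass uptake rate it computes the pool enrichment the
  spike produces, inverts the rate equation to the noise-free final atom %
  the IRMS would read, adds truncated Gaussian measurement noise, and emits
  replicate vials plus two un-amended controls.  At zero noise the rate
  pipeline recovers the true rate exactly (the forward map composed with
  the estimator is the identity).

* :func:`simulate_counts` builds an annotated marker-gene count table for a
  community of taxa with per-sample activity levels and per-pathway
  weights.  Expected read counts are proportional to activity x pathway
  weight x gene length (longer genes collect more fragments, which is what
  FPKM normalization must undo), scaled so each sample's expected total
  equals the requested depth, then Poisson-sampled (optionally
  Gamma-Poisson for overdispersed libraries).  The exact generating share
  vectors are returned for assertions.

Noise enters only through the atom % readout: masses, volumes and times
are treated as exact, because the isotope-ratio measurement is the step
with instrument error.  All draws are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import PathwayCatalog, default_catalog
from .errors import InfeasibleScenarioError, InputError
from .isotopes import (
    NATURAL_ABUNDANCE_PCT,
    IncubationMeasurement,
    TracerAddition,
    excess_enrichment,
    pom_nanomoles,
)

# ---------------------------------------------------------------------------
# Incubation simulation


@dataclass(frozen=True)
class IncubationScenario:
    """Ground truth for one simulated tracer experiment."""

    true_rho: float  # nmol per mg dry mass per hour
    spike: TracerAddition
    v_inc: float = 1e-3  # L
    nat_conc: float = 0.04e-6  # mol / L
    nat_abundance: float = NATURAL_ABUNDANCE_PCT["N"]  # atom %
    pom_mass_mg: float = 0.014
    mat_dry_mass_mg: float = 10.0
    time_inc_h: float = 6.0
    element: str = "N"
    substrate: str = "ammonium"
    noise_sd: float = 0.0  # atom %
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rho < 0:
            raise InputError("true uptake rate must be >= 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InputError("need at least one replicate")


@dataclass
class SimulatedIncubation:
    scenario: IncubationScenario
    replicates: list[IncubationMeasurement]
    controls: list[IncubationMeasurement]
    r_exc: float  # pool enrichment implied by the spike (%)
    at_f_true: float  # noise-free final atom %


def _blank_measurement(sc: IncubationScenario, at_f: float) -> IncubationMeasurement:
    return IncubationMeasurement(
        v_inc=sc.v_inc,
        nat_conc=sc.nat_conc,
        nat_abundance=sc.nat_abundance,
        at_f=at_f,
        pom_mass_mg=sc.pom_mass_mg,
        mat_dry_mass_mg=sc.mat_dry_mass_mg,
        time_inc_h=sc.time_inc_h,
        element=sc.element,
        substrate=sc.substrate,
    )


def simulate_incubation(scenario: IncubationScenario) -> SimulatedIncubation:
    """Forward observation model: true rate -> noisy atom % measurements.

    Raises :class:`InfeasibleScenarioError` when the true rate would drive
    the particulate atom % above 100 (the scenario's pool or time make the
    implied labelling physically impossible).
    """
    sc = scenario
    probe = _blank_measurement(sc, sc.nat_abundance)
    r_exc = excess_enrichment(sc.spike, probe)
    if r_exc <= 0:
        raise InfeasibleScenarioError(
            "spike produces no pool enrichment (v_add or t_conc is zero); "
            "no rate is observable"
        )
    pom_nmol = pom_nanomoles(sc.pom_mass_mg, sc.element)
    excess = sc.true_rho * r_exc * sc.mat_dry_mass_mg * sc.time_inc_h / pom_nmol
    at_f_true = sc.nat_abundance + excess
    if at_f_true > 100:
        raise InfeasibleScenarioError(
            f"true_rho = {sc.true_rho} implies final atom % "
            f"{at_f_true:.2f} > 100; limiting parameter: true_rho (or "
            "pom_mass_mg too small for this incubation time)"
        )
    rng = np.random.default_rng(sc.seed)
    at_f = at_f_true + rng.normal(0.0, sc.noise_sd, size=sc.n_replicates)
    at_ctrl = sc.nat_abundance + rng.normal(0.0, sc.noise_sd, size=2)
    at_f = np.clip(at_f, 0.0, 100.0)
    at_ctrl = np.clip(at_ctrl, 0.0, 100.0)
    reps = [_blank_measurement(sc, float(a)) for a in at_f]
    ctrls = [_blank_measurement(sc, float(a)) for a in at_ctrl]
    return SimulatedIncubation(sc, reps, ctrls, r_exc, at_f_true)


def incubation_to_table(sim: SimulatedIncubation, light: str = "light") -> pd.DataFrame:
    """Render a simulated experiment in the incubation TSV dialect."""
    sc = sim.scenario
    rows = []
    for i, m in enumerate(sim.replicates + sim.controls):
        is_control = i >= len(sim.replicates)
        rows.append(
            {
                "sample_id": f"{sc.substrate}_{'ctl' if is_control else 'rep'}{i}",
                "element": m.element,
                "substrate": m.substrate,
                "V_add_uL": 0.0 if is_control else sc.spike.v_add * 1e6,
                "T_conc_umol_L": sc.spike.t_conc * 1e6,
                "V_inc_mL": m.v_inc * 1e3,
                "Nat_conc_umol_L": m.nat_conc * 1e6,
                "AT_f_atom_pct": m.at_f,
                "POM_mass_mg": m.pom_mass_mg,
                "mat_dry_mass_mg": m.mat_dry_mass_mg,
                "time_inc_h": m.time_inc_h,
                "is_control": is_control,
                "light": light,
            }
        )
    return pd.DataFrame(rows)


#: Spike/pool parameters of the two 15N treatments used throughout the test
#: grids: 50 uL of 500 umol/L labelled ammonium chloride into 1 mL over an
#: ambient pool of 0.04 umol/L, and 30 uL of 500 umol/L labelled potassium
#: nitrate over 3.2 umol/L; 6 h incubations.
AMMONIUM_SPIKE = TracerAddition(v_add=50e-6, t_conc=500e-6)
NITRATE_SPIKE = TracerAddition(v_add=30e-6, t_conc=500e-6)


def ammonium_scenario(**kw) -> IncubationScenario:
    return IncubationScenario(
        true_rho=kw.pop("true_rho", 0.05),
        spike=kw.pop("spike", AMMONIUM_SPIKE),
        nat_conc=kw.pop("nat_conc", 0.04e-6),
        substrate=kw.pop("substrate", "ammonium"),
        **kw,
    )


def nitrate_scenario(**kw) -> IncubationScenario:
    return IncubationScenario(
        true_rho=kw.pop("true_rho", 0.05),
        spike=kw.pop("spike", NITRATE_SPIKE),
        nat_conc=kw.pop("nat_conc", 3.2e-6),
        substrate=kw.pop("substrate", "nitrate"),
        **kw,
    )


def incubation_scenario_from_yaml(path: str | Path) -> IncubationScenario:
    """Load an incubation scenario from a YAML mapping (keys = field names;
    the spike is a nested mapping ``spike: {v_add, t_conc, ...}``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spike = TracerAddition(**raw.pop("spike"))
    return IncubationScenario(spike=spike, **raw)


# ---------------------------------------------------------------------------
# Community count simulation


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: lineage, per-condition levels, pathway weights.

    ``abundance`` drives DNA-library samples, ``activity`` cDNA-library
    samples; both map condition keys ``(temperature_C, time_of_day)`` to
    non-negative levels.  ``pathway_weights`` lists the pathways whose
    marker genes this taxon carries (weight 0 keeps the genes in the
    annotation table but silent — present in the metagenome sense without
    transcription in the simulated libraries).
    """

    lineage: str
    abundance: dict
    activity: dict
    pathway_weights: dict

    def level(self, temperature_C, time_of_day, library: str) -> float:
        table = self.abundance if library == "DNA" else self.activity
        return float(table.get((temperature_C, time_of_day), 0.0))


@dataclass(frozen=True)
class CommunityScenario:
    taxa: tuple
    samples: pd.DataFrame  # sample sheet sans library_size
    depth: int = 100_000
    length_range_bp: tuple = (600, 3000)
    dispersion: float = 0.0  # Gamma-Poisson overdispersion; 0 = pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise InputError("community scenario needs at least one taxon")
        if self.depth <= 0:
            raise InputError("depth must be > 0")
        for t in self.taxa:
            for w in t.pathway_weights.values():
                if w < 0:
                    raise InputError("pathway weights must be >= 0")


@dataclass
class SimulatedCommunity:
    annotations: pd.DataFrame
    counts: pd.DataFrame  # features x samples, integer
    samples: pd.DataFrame  # full sample sheet incl. realized library_size
    truth_pathway_shares: pd.DataFrame  # pathway_id, sample_id, taxon, share_pct
    truth_taxon_shares: pd.DataFrame  # sample_id, taxon, share_pct (whole profile)


def simulate_counts(
    scenario: CommunityScenario, catalog: PathwayCatalog | None = None
) -> SimulatedCommunity:
    """Draw an annotated count table and return the generating shares.

    One feature is emitted per (taxon, marker gene of a pathway the taxon
    lists), so the default community covers every catalog symbol.  The
    expected count of a feature is proportional to
    ``level(sample) * pathway_weight * length_kb`` and expected per-sample
    totals equal ``depth``; library_size is the realized column sum.
    """
    catalog = catalog or default_catalog()
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    feat_rows = []
    weights = []  # per-feature (taxon, pathway) base weight rows
    lo, hi = sc.length_range_bp
    for ti, taxon in enumerate(sc.taxa):
        for pw_id, w in taxon.pathway_weights.items():
            for marker in catalog.markers_of(pw_id):
                length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                feat_rows.append(
                    {
                        "feature_id": f"f{len(feat_rows):05d}_{marker.symbol}",
                        "gene_symbol": marker.symbol,
                        "length_bp": length,
                        "taxon_lineage": taxon.lineage,
                    }
                )
                weights.append((ti, pw_id, float(w), length))
    if not feat_rows:
        raise InputError("no features generated: taxa list no pathways")
    annotations = pd.DataFrame(feat_rows)

    sample_ids, lib_sizes = [], []
    count_cols = {}
    truth_pw_rows, truth_tax_rows = [], []
    for srow in sc.samples.itertuples(index=False):
        sid = srow.sample_id
        sample_ids.append(sid)
        lv = np.array(
            [
                sc.taxa[ti].level(srow.temperature_C, srow.time_of_day, srow.library) * w
                for ti, _pw, w, _len in weights
            ]
        )
        len_kb = np.array([ln / 1e3 for _ti, _pw, _w, ln in weights])
        expo = lv * len_kb
        z = expo.sum()
        lam = sc.depth * expo / z if z > 0 else np.zeros_like(expo)
        if sc.dispersion > 0:
            shape = 1.0 / sc.dispersion
            lam = rng.gamma(shape, 1.0, size=lam.size) / shape * lam
        counts = rng.poisson(lam)
        count_cols[sid] = counts
        lib_sizes.append(int(counts.sum()))

        # generating shares, in normalized (length-free) terms
        pw_ids = sorted({pw for _ti, pw, _w, _ln in weights})
        for pw in pw_ids:
            idx = [i for i, (_ti, p, _w, _ln) in enumerate(weights) if p == pw]
            tot = lv[idx].sum()
            by_taxon: dict[str, float] = {}
            for i in idx:
                lineage = sc.taxa[weights[i][0]].lineage
                by_taxon[lineage] = by_taxon.get(lineage, 0.0) + lv[i]
            for lineage, v in by_taxon.items():
                truth_pw_rows.append(
                    {
                        "pathway_id": pw,
                        "sample_id": sid,
                        "taxon_lineage": lineage,
                        "share_pct": 100.0 * v / tot if tot > 0 else 0.0,
                    }
                )
        tot_all = lv.sum()
        by_taxon_all: dict[str, float] = {}
        for i, (ti, _pw, _w, _ln) in enumerate(weights):
            lineage = sc.taxa[ti].lineage
            by_taxon_all[lineage] = by_taxon_all.get(lineage, 0.0) + lv[i]
        for lineage, v in by_taxon_all.items():
            truth_tax_rows.append(
                {
                    "sample_id": sid,
                    "taxon_lineage": lineage,
                    "share_pct": 100.0 * v / tot_all if tot_all > 0 else 0.0,
                }
            )

    counts_df = pd.DataFrame(count_cols, index=annotations["feature_id"])
    counts_df.index.name = "feature_id"
    samples_df = sc.samples.copy()
    samples_df["library_size"] = lib_sizes
    return SimulatedCommunity(
        annotations=annotations,
        counts=counts_df,
        samples=samples_df,
        truth_pathway_shares=pd.DataFrame(truth_pw_rows),
        truth_taxon_shares=pd.DataFrame(truth_tax_rows),
    )


def _condition_grid(temps=(66, 58, 48), times=("day", "night"), libraries=("DNA", "cDNA")):
    rows = [
        {
            "sample_id": f"T{t}_{tod}_{lib}",
            "temperature_C": t,
            "library": lib,
            "time_of_day": tod,
        }
        for t in temps
        for tod in times
        for lib in libraries
    ]
    return pd.DataFrame(rows)


def porcelana_like_scenario(
    depth: int = 100_000, seed: int = 0, dispersion: float = 0.0
) -> CommunityScenario:
    """A synthetic hot-spring mat community (labelled synthetic throughout).

    The structure — a cyanobacterium dominating the cool (48 C) daytime
    community, filamentous anoxygenic Chloroflexi dominating at 66 C,
    heterotrophic Proteobacteria elevated at night, minor Thaumarchaeota
    (ammonia oxidation, HH-cycle carbon fixation) and a silent
    anammox-capable Planctomycete — emulates the day/night x temperature
    activity patterns typical of neutral thermal mats.  Magnitudes are
    invented for testing; only the orderings are meaningful.
    """

    def grid(d66, d58, d48, n66, n58, n48):
        return {
            (66, "day"): d66,
            (58, "day"): d58,
            (48, "day"): d48,
            (66, "night"): n66,
            (58, "night"): n58,
            (48, "night"): n48,
        }

    cyano = TaxonSpec(
        lineage="Bacteria;Cyanobacteria;Cyanophyceae;Stigonematales;Mastigocladaceae;Mastigocladus",
        abundance=grid(10, 40, 70, 10, 40, 70),
        activity=grid(5, 45, 80, 2, 20, 40),
        pathway_weights={
            "oxygenic_photosynthesis": 1.0,
            "cbb_cycle": 0.8,
            "n2_fixation": 0.4,
            "ammonia_assimilation": 0.3,
        },
    )
    chloroflexi = TaxonSpec(
        lineage="Bacteria;Chloroflexi;Chloroflexia;Chloroflexales;Chloroflexaceae;Chloroflexus",
        abundance=grid(70, 40, 15, 70, 40, 15),
        activity=grid(80, 40, 10, 40, 25, 8),
        pathway_weights={
            "anoxygenic_phototrophy": 1.0,
            "hp_bicycle": 0.6,
            "ammonia_assimilation": 0.5,
            "dnra": 0.05,
        },
    )
    proteo = TaxonSpec(
        lineage="Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;Elioraeaceae;Elioraea",
        abundance=grid(8, 12, 12, 8, 12, 12),
        activity=grid(2, 8, 6, 30, 50, 45),
        pathway_weights={
            "anoxygenic_phototrophy": 0.3,
            "denitrification": 0.4,
            "ammonia_assimilation": 0.2,
        },
    )
    thaum = TaxonSpec(
        lineage="Archaea;Thaumarchaeota;Nitrososphaeria;Nitrososphaerales;Nitrososphaeraceae;Nitrososphaera",
        abundance=grid(6, 4, 2, 6, 4, 2),
        activity=grid(10, 5, 3, 8, 4, 2),
        pathway_weights={
            "ammonia_oxidation": 1.0,
            "hh_cycle": 0.5,
        },
    )
    plancto = TaxonSpec(
        lineage="Bacteria;Planctomycetes;Planctomycetia;Candidatus Scalindua;Scalinduaceae;Scalindua",
        abundance=grid(1, 1, 1, 1, 1, 1),
        activity=grid(0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
        # weight 0: hzsA features exist in the annotations but are never
        # transcribed or sequenced -> anammox reports zero activity
        pathway_weights={"anammox": 0.0},
    )
    return CommunityScenario(
        taxa=(cyano, chloroflexi, proteo, thaum, plancto),
        samples=_condition_grid(),
        depth=depth,
        dispersion=dispersion,
        seed=seed,
    )


def write_community(sim: SimulatedCommunity, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV set the quantification pipeline consumes, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    sim.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    sim.counts.to_csv(paths["counts"], sep="\t")
    sim.samples.to_csv(paths["samples"], sep="\t", index=False)
    sim.truth_pathway_shares.to_csv(paths["truth"], sep="\t", index=False)
    return paths
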