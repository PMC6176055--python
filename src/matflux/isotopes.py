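"""Stable-isotope tracer assimilation rates.

A dual-label tracer experiment spikes an incubated sample (here, microbial
mat cores in spring water) with a heavy-isotope substrate (15NH4Cl, K15NO3
or H13CO3), incubates for a few hours, and measures by isotope-ratio mass
spectrometry (IRMS) the final atom percent of the heavy isotope in the
particulate organic fraction.  Two quantities connect that readout to an
uptake rate:

``excess_enrichment`` (%R_exc)
    the atom-% enrichment of the *dissolved* substrate pool above natural
    abundance immediately after the spike, from pool-mixing mole balance:

        A      = V_add * T_conc / V_inc          (added tracer, mol / L)
        atom%  = 100 * (A * f_t + Nat_conc * Nat_ab/100) / (Nat_conc + A)
        %R_exc = atom% - Nat_ab

    with ``f_t`` the tracer's isotopic purity (atom fraction, ~0.98-1.0).

``assimilation_rate`` (rho)
    the uptake of substrate into biomass per unit dry mass and time:

        rho = [(AT_f - Nat_ab) / %R_exc] * n_POM / m_dry / t_inc

    where ``n_POM`` is the particulate organic N or C in nanomoles
    (mass / molar mass), ``m_dry`` the analyzed mat dry mass (mg) and
    ``t_inc`` the incubation time (h); rho is nmol mg^-1 h^-1.

Rates are extrapolated to a daily areal rate (nmol cm^-2 d^-1) with the
core cross-section and a configurable photoperiod, and the pool turnover
time is the ambient concentration divided by the volumetric uptake rate.

Units: the dataclasses are unit-consistent rather than unit-fixed — the
ratios in both formulas cancel any consistent choice (SI or mL / umol L^-1
alike).  The TSV reader fixes units via its header names and converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedPoolError

#: Natural abundance of the heavy isotope, atom % (international standards:
#: air N2 for 15N, VPDB for 13C).
NATURAL_ABUNDANCE_PCT = {"N": 0.3663, "C": 1.108}

#: Molar mass of the traced element, g / mol.
MOLAR_MASS_G_MOL = {"N": 14.0067, "C": 12.011}

#: Default dissolved inorganic carbon pool for bicarbonate incubations,
#: mol / L (0.8 mM, typical of neutral hot-spring mat water).
DEFAULT_DIC_MOL_L = 0.8e-3

#: Minimum isotopic excess (atom %) regarded as above IRMS detection.
DEFAULT_DETECTION_THRESHOLD_PCT = 1e-3

SUBSTRATES = ("ammonium", "nitrate", "bicarbonate")


@dataclass(frozen=True)
class TracerAddition:
    """The spike: volume and concentration of tracer solution added.

    ``tracer_atom_fraction`` is the isotopic purity of the tracer (commercial
    tracers are 98-99 atom %; 1.0 reproduces the idealized pure-tracer form).
    """

    v_add: float  # volume added (L, or any unit shared with v_inc)
    t_conc: float  # tracer concentration (mol/L, or unit shared with nat_conc)
    tracer_atom_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.v_add < 0 or self.t_conc < 0:
            raise InputError("tracer volume and concentration must be >= 0")
        if not 0 < self.tracer_atom_fraction <= 1:
            raise InputError("tracer_atom_fraction must be in (0, 1]")


@dataclass(frozen=True)
class IncubationMeasurement:
    """One incubated vial: pool context plus the IRMS readout."""

    v_inc: float  # incubated volume (same unit as v_add)
    nat_conc: float  # ambient substrate concentration (same unit as t_conc)
    nat_abundance: float  # natural abundance of heavy isotope (atom %)
    at_f: float  # final atom % in the particulate fraction
    pom_mass_mg: float  # particulate organic N or C recovered (mg)
    mat_dry_mass_mg: float  # mat dry mass analyzed (mg)
    time_inc_h: float  # incubation duration (h)
    element: str = "N"  # traced element: "N" or "C"
    substrate: str = "ammonium"

    def __post_init__(self) -> None:
        if self.v_inc <= 0:
            raise InputError("incubated volume must be > 0")
        if self.nat_conc < 0:
            raise InputError("ambient concentration must be >= 0")
        if not 0 <= self.nat_abundance < 100:
            raise InputError("natural abundance must be in [0, 100)")
        if not 0 <= self.at_f <= 100:
            raise InputError("final atom % must be in [0, 100]")
        if min(self.pom_mass_mg, self.mat_dry_mass_mg, self.time_inc_h) <= 0:
            raise InputError("masses and incubation time must be > 0")
        if self.element not in MOLAR_MASS_G_MOL:
            raise InputError(f"element must be 'N' or 'C', got {self.element!r}")
        if self.substrate not in SUBSTRATES:
            raise InputError(f"unknown substrate {self.substrate!r}")


@dataclass(frozen=True)
class CoreGeometry:
    """Core cross-section and the photoperiod used for daily extrapolation.

    ``photoperiod_hours`` defaults to 24; set it to the daylight span to
    extrapolate light-dependent rates over daylight hours only.
    """

    diameter_cm: float = 0.7
    photoperiod_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise InputError("core diameter must be > 0")
        if not 0 < self.photoperiod_hours <= 24:
            raise InputError("photoperiod must be in (0, 24] hours")

    @property
    def area_cm2(self) -> float:
        return math.pi * (self.diameter_cm / 2.0) ** 2


@dataclass(frozen=True)
class RateResult:
    """Computed rates for one vial."""

    r_exc: float  # excess enrichment of the dissolved pool (%)
    rho_mass: float  # assimilation rate (nmol mg^-1 h^-1), clamped at 0
    rho_areal_daily: float  # daily areal rate (nmol cm^-2 d^-1)
    turnover_hours: float  # ambient pool / volumetric uptake (h); may be inf
    below_detection: bool
    rho_mass_raw: float = 0.0  # unclamped value, for diagnostics


def excess_enrichment(spike: TracerAddition, inc: IncubationMeasurement) -> float:
    """Atom-% enrichment of the dissolved pool above natural abundance.

    Raises :class:`UndefinedPoolError` when both the ambient pool and the
    spike are zero (the mixed pool has no substrate at all).
    """
    added = spike.v_add * spike.t_conc / inc.v_inc
    total = inc.nat_conc + added
    if total <= 0:
        raise UndefinedPoolError(
            "dissolved pool is empty (nat_conc = 0 and no tracer added); "
            "enrichment is undefined"
        )
    heavy = added * spike.tracer_atom_fraction + inc.nat_conc * (
        inc.nat_abundance / 100.0
    )
    return 100.0 * heavy / total - inc.nat_abundance


def assimilation_rate(
    inc: IncubationMeasurement,
    r_exc: float,
    *,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD_PCT,
    clamp: bool = True,
) -> tuple[float, bool]:
    """Per-dry-mass uptake rate (nmol mg^-1 h^-1) and a detection flag.

    Returns ``(rho, below_detection)``.  A particulate excess at or below
    ``detection_threshold`` atom % — including a negative excess, which is
    measurement noise, not negative uptake — yields rho = 0 with the flag
    set (when ``clamp`` is true; otherwise the raw signed value is
    returned).
    """
    if r_exc <= 0:
        raise InputError("excess enrichment must be > 0 to compute a rate")
    excess = inc.at_f - inc.nat_abundance
    pom_nmol = pom_nanomoles(inc.pom_mass_mg, inc.element)
    rho = (excess / r_exc) * pom_nmol / inc.mat_dry_mass_mg / inc.time_inc_h
    below = excess <= detection_threshold
    if below and clamp:
        return 0.0, True
    return rho, below


def pom_nanomoles(pom_mass_mg: float, element: str) -> float:
    """Convert particulate organic N or C mass (mg) to nanomoles."""
    try:
        molar = MOLAR_MASS_G_MOL[element]
    except KeyError:
        raise InputError(f"element must be 'N' or 'C', got {element!r}") from None
    # mg -> g is 1e-3; mol -> nmol is 1e9; net 1e6
    return pom_mass_mg / molar * 1e6


def areal_daily_rate(
    rho_mass: float, core_dry_mass_mg: float, geom: CoreGeometry
) -> float:
    """Extrapolate a per-mass hourly rate to nmol cm^-2 d^-1."""
    if core_dry_mass_mg <= 0:
        raise InputError("core dry mass must be > 0")
    return rho_mass * core_dry_mass_mg / geom.area_cm2 * geom.photoperiod_hours


def turnover_time(nat_conc: float, uptake_rate: float) -> float:
    """Pool turnover time (h): ambient concentration / volumetric uptake.

    A zero uptake rate gives ``math.inf`` (an unconsumed pool), not an
    exception; a negative rate is a domain error.
    """
    if nat_conc < 0:
        raise InputError("ambient concentration must be >= 0")
    if uptake_rate < 0:
        raise InputError("uptake rate must be >= 0")
    if uptake_rate == 0:
        return 0.0 if nat_conc == 0 else math.inf
    return nat_conc / uptake_rate


def compute_rate(
    spike: TracerAddition,
    inc: IncubationMeasurement,
    geom: CoreGeometry | None = None,
    *,
    core_dry_mass_mg: float | None = None,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD_PCT,
) -> RateResult:
    """Run the full per-vial chain: enrichment -> rate -> areal/daily -> turnover.

    ``core_dry_mass_mg`` defaults to the measurement's ``mat_dry_mass_mg``
    (i.e. the whole analyzed core); supply it separately when only a
    subsample went on the IRMS.
    """
    geom = geom or CoreGeometry()
    core_mass = core_dry_mass_mg if core_dry_mass_mg is not None else inc.mat_dry_mass_mg
    r_exc = excess_enrichment(spike, inc)
    rho, below = assimilation_rate(
        inc, r_exc, detection_threshold=detection_threshold, clamp=True
    )
    rho_raw, _ = assimilation_rate(
        inc, r_exc, detection_threshold=detection_threshold, clamp=False
    )
    rho_areal = areal_daily_rate(rho, core_mass, geom)
    # volumetric uptake for turnover: nmol mg^-1 h^-1 * mg / L -> pool units/h
    vol_uptake = rho * core_mass / inc.v_inc * 1e-9  # nmol -> mol
    tt = turnover_time(inc.nat_conc, vol_uptake)
    return RateResult(
        r_exc=r_exc,
        rho_mass=rho,
        rho_areal_daily=rho_areal,
        turnover_hours=tt,
        below_detection=below,
        rho_mass_raw=rho_raw,
    )


@dataclass(frozen=True)
class ReplicateSummary:
    mean_rho_areal_daily: float
    sd_rho_areal_daily: float
    n: int
    nat_abundance_used: float


def control_natural_abundance(
    controls: Sequence[IncubationMeasurement],
) -> float:
    """Mean final atom % of un-amended controls = measured natural abundance."""
    if not controls:
        raise InputError("no control measurements supplied")
    return float(np.mean([c.at_f for c in controls]))


def summarize_replicates(
    results: Sequence[RateResult],
    controls: Sequence[IncubationMeasurement] = (),
    *,
    nat_abundance_default: float | None = None,
) -> ReplicateSummary:
    """Mean and sample SD of the daily areal rate across replicates.

    When controls are supplied their mean atom % is reported as the natural
    abundance the rates should use (see :func:`rates_for_replicates`, which
    applies it before computing each replicate's rate).
    """
    if not results:
        raise InputError("empty replicate list")
    vals = np.array([r.rho_areal_daily for r in results], dtype=float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    nat = (
        control_natural_abundance(controls)
        if controls
        else (nat_abundance_default if nat_abundance_default is not None else float("nan"))
    )
    return ReplicateSummary(
        mean_rho_areal_daily=float(np.mean(vals)),
        sd_rho_areal_daily=sd,
        n=len(vals),
        nat_abundance_used=nat,
    )


def rates_for_replicates(
    spike: TracerAddition,
    replicates: Sequence[IncubationMeasurement],
    controls: Sequence[IncubationMeasurement] = (),
    geom: CoreGeometry | None = None,
    *,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD_PCT,
) -> tuple[list[RateResult], ReplicateSummary]:
    """Compute per-replicate rates with control-derived natural abundance.

    If un-amended controls are present, their mean atom % replaces each
    replicate's default natural abundance before any rate is computed; this
    is how field campaigns calibrate the isotopic baseline of the mat
    itself rather than relying on the international standard value.
    """
    if not replicates:
        raise InputError("empty replicate list")
    if controls:
        nat = control_natural_abundance(controls)
        replicates = [replace(r, nat_abundance=nat) for r in replicates]
    results = [
        compute_rate(spike, r, geom, detection_threshold=detection_threshold)
        for r in replicates
    ]
    summary = summarize_replicates(
        results, controls, nat_abundance_default=replicates[0].nat_abundance
    )
    return results, summary


# ---------------------------------------------------------------------------
# Tabular interface


INCUBATION_COLUMNS = [
    "sample_id",
    "element",
    "substrate",
    "V_add_uL",
    "T_conc_umol_L",
    "V_inc_mL",
    "Nat_conc_umol_L",
    "AT_f_atom_pct",
    "POM_mass_mg",
    "mat_dry_mass_mg",
    "time_inc_h",
    "is_control",
    "light",
]


def _row_measurement(row, nat_abundance: float, dic_umol_l: float) -> IncubationMeasurement:
    nat_conc = row.Nat_conc_umol_L
    if (nat_conc is None or (isinstance(nat_conc, float) and math.isnan(nat_conc))) and (
        row.substrate == "bicarbonate"
    ):
        nat_conc = dic_umol_l
    return IncubationMeasurement(
        v_inc=row.V_inc_mL * 1e-3,
        nat_conc=float(nat_conc) * 1e-6,
        nat_abundance=nat_abundance,
        at_f=row.AT_f_atom_pct,
        pom_mass_mg=row.POM_mass_mg,
        mat_dry_mass_mg=row.mat_dry_mass_mg,
        time_inc_h=row.time_inc_h,
        element=row.element,
        substrate=row.substrate,
    )


def process_incubation_table(
    table: pd.DataFrame,
    *,
    geom: CoreGeometry | None = None,
    nat_abundance_pct: dict[str, float] | None = None,
    tracer_atom_fraction: float = 1.0,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD_PCT,
    dic_umol_l: float = DEFAULT_DIC_MOL_L * 1e6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute rates for a whole incubation table.

    The table follows the vial-per-row TSV dialect (units fixed by the
    header names: uL, umol/L, mL, mg, h).  Un-amended control rows
    (``is_control`` truthy) override the element's default natural
    abundance for every treatment row of that element.  Returns
    ``(per_vial, summaries)`` frames; summaries are grouped by
    (element, substrate, light).
    """
    missing = [c for c in INCUBATION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"incubation table missing columns: {missing}")
    if table.empty:
        raise InputError("incubation table has no rows")
    geom = geom or CoreGeometry()
    defaults = dict(NATURAL_ABUNDANCE_PCT)
    if nat_abundance_pct:
        defaults.update(nat_abundance_pct)

    df = table.copy()
    df["is_control"] = df["is_control"].astype(bool)
    nat_by_element: dict[str, float] = {}
    for el, grp in df[df["is_control"]].groupby("element"):
        nat_by_element[el] = float(grp["AT_f_atom_pct"].mean())

    per_vial_rows = []
    for row in df[~df["is_control"]].itertuples(index=False):
        nat = nat_by_element.get(row.element, defaults.get(row.element))
        if nat is None:
            raise InputError(f"no natural abundance known for element {row.element!r}")
        spike = TracerAddition(
            v_add=row.V_add_uL * 1e-6,
            t_conc=row.T_conc_umol_L * 1e-6,
            tracer_atom_fraction=tracer_atom_fraction,
        )
        inc = _row_measurement(row, nat, dic_umol_l)
        res = compute_rate(
            spike, inc, geom, detection_threshold=detection_threshold
        )
        per_vial_rows.append(
            {
                "sample_id": row.sample_id,
                "element": row.element,
                "substrate": row.substrate,
                "light": row.light,
                "nat_abundance_pct": nat,
                "R_exc_pct": res.r_exc,
                "rho_nmol_mg_h": res.rho_mass,
                "rho_nmol_cm2_d": res.rho_areal_daily,
                "turnover_h": res.turnover_hours,
                "below_detection": res.below_detection,
                "rho_raw_nmol_mg_h": res.rho_mass_raw,
            }
        )
    per_vial = pd.DataFrame(per_vial_rows)
    if per_vial.empty:
        raise InputError("incubation table contains only control rows")

    summaries = (
        per_vial.groupby(["element", "substrate", "light"], as_index=False)
        .agg(
            mean_rho_nmol_cm2_d=("rho_nmol_cm2_d", "mean"),
            sd_rho_nmol_cm2_d=("rho_nmol_cm2_d", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n=("rho_nmol_cm2_d", "size"),
            mean_turnover_h=("turnover_h", "mean"),
            nat_abundance_pct=("nat_abundance_pct", "first"),
        )
    )
    return per_vial, summaries


def read_incubation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df
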