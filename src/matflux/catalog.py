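"""Pathway -> marker-gene catalogs.

Pathway activity in metagenomes/metatranscriptomes is quantified through a
small set of indicator ("marker") genes: a transcript of *rbcL* indicates
Calvin-Benson-Bassham carbon fixation, *nifH* nitrogen fixation, *amoA*
ammonia oxidation, and so on.  A :class:`PathwayCatalog` maps each marker
symbol to exactly one pathway and carries the pathway's broad process class.

The packaged default catalog covers oxygenic and anoxygenic phototrophy,
three CO2-fixation pathways (CBB, 3-hydroxypropionate bi-cycle,
hydroxypropionate-hydroxybutyrate cycle) and six nitrogen transformations
(N2 fixation, ammonia assimilation, ammonia oxidation, DNRA,
denitrification, anammox).  Users extend it with their own tab-separated
file (header ``symbol  pathway_id  pathway_name  process_class``; ``#``
comments allowed).

Symbol matching is case-insensitive everywhere: annotation pipelines differ
in casing (``pufM`` vs ``PufM``), and a catalog may not contain the same
symbol twice even under different casings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CatalogError

PROCESS_CLASSES = frozenset(
    {
        "oxygenic_photosynthesis",
        "anoxygenic_phototrophy",
        "carbon_fixation",
        "nitrogen_cycle",
    }
)

_CATALOG_COLUMNS = ["symbol", "pathway_id", "pathway_name", "process_class"]


@dataclass(frozen=True)
class MarkerGene:
    """One indicator gene: ``symbol`` marks pathway ``pathway_id``."""

    symbol: str
    pathway_id: str
    process_class: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogError("marker gene symbol must be non-empty")
        if self.process_class not in PROCESS_CLASSES:
            raise CatalogError(
                f"unknown process_class {self.process_class!r} for symbol "
                f"{self.symbol!r}; expected one of {sorted(PROCESS_CLASSES)}"
            )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    process_class: str


@dataclass
class PathwayCatalog:
    """A validated set of pathways and the marker genes indicating them."""

    pathways: dict[str, Pathway] = field(default_factory=dict)
    markers: list[MarkerGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_symbol: dict[str, MarkerGene] = {}
        for m in self.markers:
            key = m.symbol.lower()
            if key in self._by_symbol:
                raise CatalogError(f"duplicate marker symbol {m.symbol!r}")
            if m.pathway_id not in self.pathways:
                raise CatalogError(
                    f"marker {m.symbol!r} references unknown pathway "
                    f"{m.pathway_id!r}"
                )
            self._by_symbol[key] = m

    # -- queries ---------------------------------------------------------

    @property
    def symbols(self) -> list[str]:
        """Canonical marker symbols, in catalog order."""
        return [m.symbol for m in self.markers]

    def marker(self, symbol: str) -> MarkerGene:
        """Look up a marker by symbol (case-insensitive)."""
        try:
            return self._by_symbol[symbol.lower()]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in catalog") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.lower() in self._by_symbol

    def pathway_of(self, symbol: str) -> str:
        return self.marker(symbol).pathway_id

    def markers_of(self, pathway_id: str) -> list[MarkerGene]:
        return [m for m in self.markers if m.pathway_id == pathway_id]

    def __len__(self) -> int:
        return len(self.markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCatalog):
            return NotImplemented
        return (
            set(self.pathways.values()) == set(other.pathways.values())
            and set(self.markers) == set(other.markers)
        )

    # -- construction ----------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PathwayCatalog":
        missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise CatalogError(f"catalog file missing columns: {missing}")
        pathways: dict[str, Pathway] = {}
        markers: list[MarkerGene] = []
        for row in df.itertuples(index=False):
            pid = str(row.pathway_id)
            pw = Pathway(pid, str(row.pathway_name), str(row.process_class))
            if pid in pathways and pathways[pid] != pw:
                raise CatalogError(
                    f"pathway {pid!r} declared with inconsistent "
                    "name/process_class"
                )
            pathways[pid] = pw
            markers.append(
                MarkerGene(str(row.symbol), pid, str(row.process_class))
            )
        return cls(pathways=pathways, markers=markers)


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load and validate a catalog from a tab-separated file.

    Raises :class:`~matflux.errors.CatalogError` on duplicate symbols,
    unknown process classes or missing columns.  An empty file (or a file of
    comments only) yields an empty catalog.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return PathwayCatalog()
    if df.empty and list(df.columns) == []:
        return PathwayCatalog()
    return PathwayCatalog.from_frame(df)


def write_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    """Write a catalog in the same TSV dialect :func:`load_catalog` reads."""
    rows = [
        {
            "symbol": m.symbol,
            "pathway_id": m.pathway_id,
            "pathway_name": catalog.pathways[m.pathway_id].name,
            "process_class": m.process_class,
        }
        for m in catalog.markers
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def default_catalog() -> PathwayCatalog:
    """The packaged default catalog (21 marker genes over 11 pathways)."""
    ref = resources.files("matflux").joinpath("data/default_catalog.tsv")
    with resources.as_file(ref) as p:
        return load_catalog(p)


def validate_annotations(
    catalog: PathwayCatalog, annotations: pd.DataFrame | Iterable
) -> pd.DataFrame:
    """Report how many annotation features carry each catalog symbol.

    ``annotations`` is an annotation table (or anything with a
    ``gene_symbol`` column / attribute per record).  Returns a frame with
    one row per catalog marker: ``symbol``, ``pathway_id``, ``n_features``,
    ``matched``.  Symbols with ``n_features == 0`` identify pathways that
    will report zero activity — a meaningful outcome (e.g. the absence of
    hydrazine synthase, *hzsA*, from a metagenome rules out detectable
    anammox), so this is report-only and never raises.
    """
    if isinstance(annotations, pd.DataFrame):
        symbols = annotations.get("gene_symbol", pd.Series(dtype=str))
    else:
        symbols = pd.Series(
            [getattr(a, "gene_symbol", "") for a in annotations], dtype=str
        )
    counts: Mapping[str, int] = (
        symbols.fillna("").str.lower().value_counts().to_dict()
    )
    rows = []
    for m in catalog.markers:
        n = int(counts.get(m.symbol.lower(), 0))
        rows.append(
            {
                "symbol": m.symbol,
                "pathway_id": m.pathway_id,
                "n_features": n,
                "matched": n > 0,
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "pathway_id", "n_features", "matched"])
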