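"""Marker-gene transcription profiles from metagenome/metatranscriptome counts.

Inputs are the downstream contracts of a standard shotgun pipeline: a
feature (predicted-gene) annotation table carrying marker symbol, length
and taxonomic lineage, and a features x samples matrix of mapped-read
counts with per-sample library sizes.  From these the module computes:

* FPKM normalization (fragments per kilobase of gene per million library
  reads) — the descriptive normalization used for marker-gene surveys;
* per-gene percent-of-total transcripts across a sample set (the "which
  temperature / time of day does this gene fire in" profile);
* summed marker-gene activity per pathway;
* per-taxon percent contribution to each pathway's transcription, at a
  chosen taxonomic rank, with minor taxa pooled into "Other";
* DNA vs cDNA share ratios per taxon (an activity index exposing the
  decoupling between a taxon's abundance and its transcription).

The count matrix holds only marker-gene features — a small subset of the
library — so library sizes are supplied in the sample sheet (total
high-quality non-rRNA reads), never recomputed from the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog
from .errors import InputError

#: Lineage string ranks, outermost first, as "domain;phylum;...;genus".
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

ANNOTATION_COLUMNS = ["feature_id", "gene_symbol", "length_bp", "taxon_lineage"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "temperature_C", "library", "time_of_day", "library_size"]

UNCLASSIFIED = "Unclassified"
OTHER = "Other"


@dataclass
class CountTable:
    """Counts matrix (features x samples) plus the sample sheet.

    ``samples`` has one row per matrix column: sample_id, temperature_C,
    library (DNA or cDNA), time_of_day (day or night), library_size.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample sheet missing columns: {missing}")
        self.samples = self.samples.set_index("sample_id", drop=False)
        unknown = [s for s in self.counts.columns if s not in self.samples.index]
        if unknown:
            raise InputError(f"samples in counts but not in sheet: {unknown[:10]}")
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][:10].tolist()
            raise InputError(f"duplicate feature ids: {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        libs = self.samples.loc[self.counts.columns, "library_size"]
        short = libs[libs < colsums]
        if len(short):
            raise InputError(
                "library_size smaller than column sum for samples: "
                f"{short.index.tolist()[:10]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.samples.loc[self.counts.columns, "library_size"].astype(float)


def validate_features(counts: pd.DataFrame, annotations: pd.DataFrame) -> None:
    """Every counted feature must be annotated (with a length)."""
    ann_ids = set(annotations["feature_id"])
    missing = [f for f in counts.index if f not in ann_ids]
    if missing:
        raise InputError(
            f"{len(missing)} features lack annotations; first offenders: "
            f"{missing[:10]}"
        )


def normalize_fpkm(table: CountTable, annotations: pd.DataFrame) -> pd.DataFrame:
    """FPKM: counts / (length/1e3) / (library_size/1e6), per feature x sample."""
    validate_features(table.counts, annotations)
    lengths = (
        annotations.set_index("feature_id")["length_bp"]
        .reindex(table.counts.index)
        .astype(float)
    )
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:10].tolist()
        raise InputError(f"non-positive gene lengths for features: {bad}")
    libs = table.library_sizes()
    if (libs <= 0).any():
        raise InputError("library sizes must be > 0")
    return table.counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


@dataclass(frozen=True)
class GenePercent:
    """Percent of a gene's total normalized transcripts found in each sample."""

    symbol: str
    percent: pd.Series  # indexed by sample id, sums to 100 unless zero_total
    zero_total: bool


def _symbol_mask(annotations: pd.DataFrame, symbol: str) -> pd.Series:
    return annotations["gene_symbol"].fillna("").str.lower() == symbol.lower()


def gene_percent_across_samples(
    profile: pd.DataFrame,
    annotations: pd.DataFrame,
    symbol: str,
    samples: list[str] | None = None,
) -> GenePercent:
    """Distribute a marker gene's total normalized abundance over samples.

    Sums the profile over all features carrying ``symbol``, restricted to
    ``samples`` (default: every column), and expresses each sample as a
    percent of the total over that subset.  A gene with zero total signal
    yields an all-zero vector flagged ``zero_total``.
    """
    mask = _symbol_mask(annotations, symbol)
    if not mask.any():
        raise InputError(f"symbol {symbol!r} has no annotated features")
    feats = annotations.loc[mask, "feature_id"]
    cols = list(profile.columns) if samples is None else list(samples)
    sub = profile.loc[profile.index.isin(feats), cols]
    per_sample = sub.sum(axis=0)
    total = float(per_sample.sum())
    if total == 0:
        return GenePercent(symbol, per_sample * 0.0, True)
    return GenePercent(symbol, per_sample / total * 100.0, False)


def pathway_activity(
    profile: pd.DataFrame,
    annotations: pd.DataFrame,
    catalog: PathwayCatalog,
) -> pd.DataFrame:
    """Summed normalized marker abundance per (pathway, sample).

    Pathways whose markers match no feature report 0, never go missing:
    the absence of a marker (e.g. hydrazine synthase for anammox) is a
    finding, not a gap.
    """
    ann = annotations.copy()
    ann["_sym"] = ann["gene_symbol"].fillna("").str.lower()
    sym_to_pw = {m.symbol.lower(): m.pathway_id for m in catalog.markers}
    ann["_pw"] = ann["_sym"].map(sym_to_pw)
    rows = []
    by_pw = {
        pw: grp["feature_id"]
        for pw, grp in ann.dropna(subset=["_pw"]).groupby("_pw")
    }
    for pw in catalog.pathways:
        feats = by_pw.get(pw)
        if feats is None:
            sums = pd.Series(0.0, index=profile.columns)
        else:
            sums = profile.loc[profile.index.isin(feats)].sum(axis=0)
        for sample, v in sums.items():
            rows.append({"pathway_id": pw, "sample_id": sample, "activity": float(v)})
    return pd.DataFrame(rows, columns=["pathway_id", "sample_id", "activity"])


def lineage_at_rank(lineage: str, rank: str) -> str:
    """Extract one rank from a semicolon-delimited lineage string."""
    try:
        idx = LINEAGE_RANKS.index(rank)
    except ValueError:
        raise InputError(
            f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}"
        ) from None
    parts = [p.strip() for p in str(lineage or "").split(";")]
    if idx < len(parts) and parts[idx]:
        return parts[idx]
    return UNCLASSIFIED


def taxon_contribution(
    profile: pd.DataFrame,
    annotations: pd.DataFrame,
    catalog: PathwayCatalog,
    rank: str = "genus",
    min_share: float = 1.0,
) -> pd.DataFrame:
    """Percent contribution of each taxon to each pathway's transcription.

    Within every (pathway, sample) cell the features are grouped by taxon
    at ``rank`` and their normalized abundance expressed as percent shares.
    Taxa below ``min_share`` percent are pooled into "Other"; lineages
    that do not resolve to ``rank`` report as "Unclassified".  Returns a
    tidy frame: pathway_id, sample_id, taxon, share_pct, zero_total.
    """
    ann = annotations.copy()
    ann["_sym"] = ann["gene_symbol"].fillna("").str.lower()
    sym_to_pw = {m.symbol.lower(): m.pathway_id for m in catalog.markers}
    ann["_pw"] = ann["_sym"].map(sym_to_pw)
    ann = ann.dropna(subset=["_pw"])
    ann["_taxon"] = ann["taxon_lineage"].map(lambda s: lineage_at_rank(s, rank))

    rows = []
    for pw in catalog.pathways:
        sub_ann = ann[ann["_pw"] == pw]
        feats = sub_ann.set_index("feature_id")["_taxon"]
        sub = profile.loc[profile.index.isin(feats.index)]
        for sample in profile.columns:
            if sub.empty:
                rows.append(
                    {
                        "pathway_id": pw,
                        "sample_id": sample,
                        "taxon": UNCLASSIFIED,
                        "share_pct": 0.0,
                        "zero_total": True,
                    }
                )
                continue
            by_taxon = sub[sample].groupby(feats.reindex(sub.index)).sum()
            total = float(by_taxon.sum())
            if total == 0:
                for taxon in by_taxon.index:
                    rows.append(
                        {
                            "pathway_id": pw,
                            "sample_id": sample,
                            "taxon": taxon,
                            "share_pct": 0.0,
                            "zero_total": True,
                        }
                    )
                continue
            shares = by_taxon / total * 100.0
            minor = shares[shares < min_share]
            major = shares[shares >= min_share]
            for taxon, pct in major.items():
                rows.append(
                    {
                        "pathway_id": pw,
                        "sample_id": sample,
                        "taxon": taxon,
                        "share_pct": float(pct),
                        "zero_total": False,
                    }
                )
            if len(minor):
                rows.append(
                    {
                        "pathway_id": pw,
                        "sample_id": sample,
                        "taxon": OTHER,
                        "share_pct": float(minor.sum()),
                        "zero_total": False,
                    }
                )
    return pd.DataFrame(
        rows, columns=["pathway_id", "sample_id", "taxon", "share_pct", "zero_total"]
    )


def dna_rna_decoupling(
    profile: pd.DataFrame,
    annotations: pd.DataFrame,
    samples: pd.DataFrame,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Per-taxon DNA share vs cDNA share and their ratio (activity index).

    Samples are paired by (temperature_C, time_of_day); each pair must have
    exactly one DNA and one cDNA library.  For every taxon at ``rank`` the
    function reports its share of the pair's total DNA signal, its share of
    the cDNA signal, and cDNA/DNA — the index whose departure from 1
    quantifies abundance/activity decoupling.  A taxon absent from DNA but
    transcribed gets an infinite ratio flag.
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id", drop=False)
    taxa = annotations.set_index("feature_id")["taxon_lineage"].map(
        lambda s: lineage_at_rank(s, rank)
    )
    taxa = taxa.reindex(profile.index).fillna(UNCLASSIFIED)

    rows = []
    for (temp, tod), grp in samples.groupby(["temperature_C", "time_of_day"]):
        dna = grp[grp["library"] == "DNA"]
        cdna = grp[grp["library"] == "cDNA"]
        if len(dna) != 1 or len(cdna) != 1:
            raise InputError(
                f"unpaired samples for temperature {temp} / {tod}: "
                f"{len(dna)} DNA and {len(cdna)} cDNA libraries"
            )
        dna_id, cdna_id = dna.index[0], cdna.index[0]
        if dna_id not in profile.columns or cdna_id not in profile.columns:
            raise InputError(
                f"paired sample missing from profile: {dna_id} / {cdna_id}"
            )
        dna_by_taxon = profile[dna_id].groupby(taxa).sum()
        cdna_by_taxon = profile[cdna_id].groupby(taxa).sum()
        dna_total = float(dna_by_taxon.sum())
        cdna_total = float(cdna_by_taxon.sum())
        for taxon in dna_by_taxon.index.union(cdna_by_taxon.index):
            d = float(dna_by_taxon.get(taxon, 0.0)) / dna_total * 100 if dna_total else 0.0
            c = float(cdna_by_taxon.get(taxon, 0.0)) / cdna_total * 100 if cdna_total else 0.0
            if d == 0:
                ratio, infinite = (np.nan, c > 0)
            else:
                ratio, infinite = (c / d, False)
            rows.append(
                {
                    "temperature_C": temp,
                    "time_of_day": tod,
                    "taxon": taxon,
                    "dna_share_pct": d,
                    "cdna_share_pct": c,
                    "activity_index": ratio,
                    "infinite_ratio": infinite,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "temperature_C",
            "time_of_day",
            "taxon",
            "dna_share_pct",
            "cdna_share_pct",
            "activity_index",
            "infinite_ratio",
        ],
    )


# ---------------------------------------------------------------------------
# Tabular IO


def read_annotations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation table missing columns: {missing}")
    if not df["feature_id"].is_unique:
        dup = df["feature_id"][df["feature_id"].duplicated()][:10].tolist()
        raise InputError(f"duplicate feature ids in annotations: {dup}")
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    if "feature_id" not in df.columns:
        raise InputError("counts table must have a feature_id first column")
    return df.set_index("feature_id")


def read_sample_sheet_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"sample sheet missing columns: {missing}")
    return df
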