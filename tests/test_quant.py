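import numpy as np
import pandas as pd
import pytest

from matflux.errors import InputError
from matflux.quant import (
    CountTable,
    dna_rna_decoupling,
    gene_percent_across_samples,
    lineage_at_rank,
    normalize_fpkm,
    pathway_activity,
    taxon_contribution,
)


class TestFpkm:
    def test_normalization_formula(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        # count 1000 over; f1: 30 reads, 1 kb gene, 1e6 library -> 30
        assert fpkm.loc["f1", "s_day"] == pytest.approx(30.0)
        # f2: 100 reads, 0.5 kb -> 200
        assert fpkm.loc["f2", "s_day"] == pytest.approx(200.0)
        assert fpkm.loc["f2", "s_night"] == 0.0

    def test_reference_values(self):
        ann = pd.DataFrame(
            {
                "feature_id": ["a", "b"],
                "gene_symbol": ["rbcL", "nifH"],
                "length_bp": [1000, 500],
                "taxon_lineage": ["B;C", "B;C"],
            }
        )
        counts = pd.DataFrame(
            {"s1": [1000, 250]}, index=pd.Index(["a", "b"], name="feature_id")
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "temperature_C": [58],
                "library": ["cDNA"],
                "time_of_day": ["day"],
                "library_size": [5_000_000],
            }
        )
        fpkm = normalize_fpkm(CountTable(counts=counts, samples=samples), ann)
        # 1000 / 1 kb / 5M reads = 200; 250 / 0.5 / 5 = 100
        assert fpkm.loc["a", "s1"] == pytest.approx(200.0)
        assert fpkm.loc["b", "s1"] == pytest.approx(100.0)

    def test_scale_invariance(self, toy_counts, toy_annotations):
        base = normalize_fpkm(toy_counts, toy_annotations)
        scaled_table = CountTable(
            counts=toy_counts.counts * 7,
            samples=toy_counts.samples.assign(
                library_size=toy_counts.samples["library_size"] * 7
            ),
        )
        scaled = normalize_fpkm(scaled_table, toy_annotations)
        pd.testing.assert_frame_equal(base, scaled)

    def test_missing_annotation_lists_offenders(self, toy_counts, toy_annotations):
        with pytest.raises(InputError, match="f4"):
            normalize_fpkm(toy_counts, toy_annotations[toy_annotations.feature_id != "f4"])

    def test_library_size_must_cover_column_sums(self, toy_counts):
        with pytest.raises(InputError, match="library_size"):
            CountTable(
                counts=toy_counts.counts,
                samples=toy_counts.samples.assign(library_size=[10, 10]),
            )


class TestGenePercent:
    def test_two_sample_toy_split(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        gp = gene_percent_across_samples(fpkm, toy_annotations, "nifH")
        assert gp.percent["s_day"] == pytest.approx(75.0)
        assert gp.percent["s_night"] == pytest.approx(25.0)
        assert not gp.zero_total

    def test_sums_over_all_features_of_a_symbol(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        gp = gene_percent_across_samples(fpkm, toy_annotations, "rbcL")
        # day: 200 + 5; night: 0 + 20
        assert gp.percent["s_day"] == pytest.approx(100 * 205 / 225)
        assert gp.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_sample_gets_everything(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        gp = gene_percent_across_samples(fpkm, toy_annotations, "nifH", ["s_day"])
        assert gp.percent.tolist() == [100.0]

    def test_zero_total_flagged(self, toy_counts, toy_annotations):
        counts = toy_counts.counts.copy()
        counts.loc["f1"] = 0
        table = CountTable(counts=counts, samples=toy_counts.samples)
        fpkm = normalize_fpkm(table, toy_annotations)
        gp = gene_percent_across_samples(fpkm, toy_annotations, "nifH")
        assert gp.zero_total and (gp.percent == 0).all()

    def test_unknown_symbol_is_an_error(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        with pytest.raises(InputError):
            gene_percent_across_samples(fpkm, toy_annotations, "nosZ")

    def test_case_insensitive_symbol_matching(self, toy_counts, toy_annotations):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        gp = gene_percent_across_samples(fpkm, toy_annotations, "NifH")
        assert gp.percent["s_day"] == pytest.approx(75.0)


class TestPathwayActivity:
    def test_sums_markers_and_reports_zero_pathways(
        self, toy_counts, toy_annotations, catalog
    ):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        act = pathway_activity(fpkm, toy_annotations, catalog)
        assert set(act["pathway_id"]) == set(catalog.pathways)
        wide = act.pivot(index="pathway_id", columns="sample_id", values="activity")
        assert wide.loc["cbb_cycle", "s_day"] == pytest.approx(205.0)
        assert wide.loc["n2_fixation", "s_night"] == pytest.approx(10.0)
        # no hzsA features anywhere: anammox present and exactly zero
        assert (wide.loc["anammox"] == 0).all()

    def test_multi_gene_pathway_additivity(self, catalog):
        ann = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "gene_symbol": ["mcl", "mcr", "prpE"],
                "length_bp": [1000, 1000, 1000],
                "taxon_lineage": ["B;Chloroflexi"] * 3,
            }
        )
        profile = pd.DataFrame(
            {"s1": [2.0, 3.0, 5.0]}, index=pd.Index(["a", "b", "c"], name="feature_id")
        )
        act = pathway_activity(profile, ann, catalog)
        wide = act.set_index(["pathway_id", "sample_id"])["activity"]
        assert wide[("hp_bicycle", "s1")] == pytest.approx(10.0)


class TestTaxonContribution:
    def _frame(self, shares):
        ann = pd.DataFrame(
            {
                "feature_id": [f"g{i}" for i in range(len(shares))],
                "gene_symbol": ["rbcL"] + ["RbcL"] * (len(shares) - 1),
                "length_bp": [1000] * len(shares),
                "taxon_lineage": [
                    f"Bacteria;Phy{i};C;O;F;Genus{i}" for i in range(len(shares))
                ],
            }
        )
        profile = pd.DataFrame(
            {"s1": list(shares)},
            index=pd.Index(ann["feature_id"], name="feature_id"),
        )
        return ann, profile

    def test_single_genus_gets_hundred_percent(self, catalog):
        ann, profile = self._frame([42.0])
        out = taxon_contribution(profile, ann, catalog, rank="genus", min_share=1.0)
        row = out[(out.pathway_id == "cbb_cycle") & (out.sample_id == "s1")]
        assert row["share_pct"].tolist() == [100.0]

    def test_ninety_ten_split(self, catalog):
        ann, profile = self._frame([90.0, 10.0])
        out = taxon_contribution(profile, ann, catalog, rank="genus", min_share=1.0)
        got = (
            out[(out.pathway_id == "cbb_cycle")]
            .set_index("taxon")["share_pct"]
            .to_dict()
        )
        assert got["Genus0"] == pytest.approx(90.0)
        assert got["Genus1"] == pytest.approx(10.0)

    def test_minor_taxa_pool_into_other(self, catalog):
        ann, profile = self._frame([80.0, 15.0, 5.0])
        out = taxon_contribution(profile, ann, catalog, rank="genus", min_share=10.0)
        got = (
            out[(out.pathway_id == "cbb_cycle")]
            .set_index("taxon")["share_pct"]
            .to_dict()
        )
        assert got == pytest.approx({"Genus0": 80.0, "Genus1": 15.0, "Other": 5.0})

    def test_shares_close_to_hundred(self, catalog):
        ann, profile = self._frame([33.0, 21.0, 11.0, 7.0])
        out = taxon_contribution(profile, ann, catalog, rank="phylum", min_share=1.0)
        sums = out[~out.zero_total].groupby(["pathway_id", "sample_id"]).share_pct.sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_missing_rank_reports_unclassified(self, catalog):
        ann, profile = self._frame([10.0])
        ann.loc[0, "taxon_lineage"] = "Bacteria;Cyanobacteria"  # no genus
        out = taxon_contribution(profile, ann, catalog, rank="genus")
        row = out[(out.pathway_id == "cbb_cycle") & (out.share_pct > 0)]
        assert row["taxon"].tolist() == ["Unclassified"]

    def test_lineage_rank_extraction(self):
        lin = "Bacteria;Cyanobacteria;Cyanophyceae;Nostocales;Hapalosiphonaceae;Mastigocladus"
        assert lineage_at_rank(lin, "phylum") == "Cyanobacteria"
        assert lineage_at_rank(lin, "genus") == "Mastigocladus"
        assert lineage_at_rank("Bacteria", "genus") == "Unclassified"
        with pytest.raises(InputError):
            lineage_at_rank(lin, "species")


class TestDecoupling:
    def _paired(self, dna_counts, cdna_counts):
        ann = pd.DataFrame(
            {
                "feature_id": ["a", "b"],
                "gene_symbol": ["rbcL", "pufM"],
                "length_bp": [1000, 1000],
                "taxon_lineage": [
                    "Bacteria;Cyanobacteria;C;O;F;G",
                    "Bacteria;Chloroflexi;C;O;F;G",
                ],
            }
        )
        profile = pd.DataFrame(
            {"dna": dna_counts, "cdna": cdna_counts},
            index=pd.Index(["a", "b"], name="feature_id"),
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["dna", "cdna"],
                "temperature_C": [58, 58],
                "library": ["DNA", "cDNA"],
                "time_of_day": ["day", "day"],
                "library_size": [100, 100],
            }
        )
        return ann, profile, samples

    def test_identical_profiles_all_ratios_one(self):
        ann, profile, samples = self._paired([60.0, 40.0], [60.0, 40.0])
        out = dna_rna_decoupling(profile, ann, samples, rank="phylum")
        assert np.allclose(out["activity_index"], 1.0)

    def test_half_activity_index(self):
        ann, profile, samples = self._paired([50.0, 50.0], [25.0, 75.0])
        out = dna_rna_decoupling(profile, ann, samples, rank="phylum")
        cy = out[out.taxon == "Cyanobacteria"].iloc[0]
        assert cy["activity_index"] == pytest.approx(0.5)

    def test_absent_from_dna_flags_infinite(self):
        ann, profile, samples = self._paired([0.0, 100.0], [30.0, 70.0])
        out = dna_rna_decoupling(profile, ann, samples, rank="phylum")
        cy = out[out.taxon == "Cyanobacteria"].iloc[0]
        assert cy["infinite_ratio"] and np.isnan(cy["activity_index"])

    def test_unpaired_samples_rejected(self):
        ann, profile, samples = self._paired([1.0, 1.0], [1.0, 1.0])
        samples.loc[1, "time_of_day"] = "night"
        with pytest.raises(InputError, match="unpaired"):
            dna_rna_decoupling(profile, ann, samples, rank="phylum")


class TestStructuralInvariants:
    def test_permutation_invariance(self, toy_counts, toy_annotations, catalog):
        fpkm = normalize_fpkm(toy_counts, toy_annotations)
        act = pathway_activity(fpkm, toy_annotations, catalog)
        perm_counts = toy_counts.counts.iloc[::-1, ::-1]
        perm_table = CountTable(counts=perm_counts, samples=toy_counts.samples)
        perm_ann = toy_annotations.iloc[::-1].reset_index(drop=True)
        act2 = pathway_activity(
            normalize_fpkm(perm_table, perm_ann), perm_ann, catalog
        )
        key = ["pathway_id", "sample_id"]
        pd.testing.assert_frame_equal(
            act.sort_values(key).reset_index(drop=True),
            act2.sort_values(key).reset_index(drop=True),
        )

    def test_count_fraction_conservation_under_grouping(
        self, toy_counts, toy_annotations
    ):
        # grouping features by symbol neither creates nor destroys reads
        frac = toy_counts.counts.div(toy_counts.library_sizes(), axis=1)
        by_symbol = frac.groupby(
            toy_annotations.set_index("feature_id")["gene_symbol"]
        ).sum()
        assert np.allclose(by_symbol.sum(axis=0), frac.sum(axis=0))
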