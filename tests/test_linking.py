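"""Peak-to-gene linkage: reference points, strand-aware windows, dedup."""

import numpy as np
import pandas as pd

from ifnsynergy.io import GenomicInterval
from ifnsynergy.linking import (
    distance_distribution,
    distance_summary,
    link_peak,
    link_peaks,
    link_summary,
    peak_reference_point,
    unique_gene_table,
)


def ann(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestReferencePoint:
    def test_midpoint(self):
        assert peak_reference_point(GenomicInterval("c", 100, 300)) == 200

    def test_midpoint_floor_tie_break(self):
        assert peak_reference_point(GenomicInterval("c", 100, 301)) == 200

    def test_summit_wins(self):
        assert peak_reference_point(GenomicInterval("c", 100, 300, summit=250)) == 250


class TestLinkPeak:
    def test_peak_at_tss_is_promoter_distance_zero(self):
        a = ann(("g1", "c", 200, "+"))
        link = link_peak(GenomicInterval("c", 100, 300, name="p"), a, {"g1"})
        assert link["signed_distance"] == 0 and link["promoter"]

    def test_minus_strand_window_is_strand_aware(self):
        # midpoint 500 bp 5' of a minus-strand TSS = genomic TSS+500
        a = ann(("g1", "c", 1000, "-"))
        link = link_peak(GenomicInterval("c", 1400, 1600, name="p"), a, {"g1"})
        assert link["signed_distance"] == -500 and link["promoter"]

    def test_2kb_upstream_not_promoter(self):
        a = ann(("g1", "c", 5000, "+"))
        link = link_peak(GenomicInterval("c", 2900, 3100, name="p"), a, {"g1"})
        assert link["signed_distance"] == -2000 and not link["promoter"]

    def test_boundaries_inclusive(self):
        a = ann(("g1", "c", 5000, "+"))
        at_low = link_peak(GenomicInterval("c", 3900, 4100, name="p"), a, {"g1"})
        assert at_low["signed_distance"] == -1000 and at_low["promoter"]
        at_high = link_peak(GenomicInterval("c", 5000, 5200, name="p"), a, {"g1"})
        assert at_high["signed_distance"] == 100 and at_high["promoter"]

    def test_only_expressed_genes_eligible(self):
        a = ann(("g1", "c", 210, "+"), ("g2", "c", 5000, "+"))
        link = link_peak(GenomicInterval("c", 100, 300, name="p"), a, {"g2"})
        assert link["gene_id"] == "g2"

    def test_no_expressed_gene_on_chrom_unassigned(self):
        a = ann(("g1", "other", 100, "+"))
        link = link_peak(GenomicInterval("c", 100, 300, name="p"), a, {"g1"})
        assert link["unassigned"]

    def test_tie_breaks_lexicographic(self):
        a = ann(("gB", "c", 100, "+"), ("gA", "c", 300, "+"))
        link = link_peak(GenomicInterval("c", 100, 300, name="p"), a, {"gA", "gB"})
        assert link["gene_id"] == "gA"


class TestUniqueGeneTable:
    def links(self, *rows):
        return pd.DataFrame(
            rows,
            columns=["peak_id", "gene_id", "signed_distance", "abs_distance", "promoter", "unassigned", "category"],
        )

    def test_promoter_link_precedence(self):
        table = unique_gene_table(
            self.links(
                ("p1", "g1", 4000, 4000, False, False, "GAS"),
                ("p2", "g1", -50, 50, True, False, "ISRE"),
            )
        )
        assert table.loc["g1", "peak_id"] == "p2"
        assert table.loc["g1", "category"] == "ISRE"
        assert bool(table.loc["g1", "promoter"])

    def test_nearest_among_distal(self):
        table = unique_gene_table(
            self.links(
                ("p1", "g1", 5000, 5000, False, False, "GAS"),
                ("p2", "g1", 3000, 3000, False, False, "GAS"),
            )
        )
        assert table.loc["g1", "peak_id"] == "p2"

    def test_distinct_genes_keep_all_rows(self):
        table = unique_gene_table(
            self.links(
                ("p1", "g1", 0, 0, True, False, "GAS"),
                ("p2", "g2", 0, 0, True, False, "ISRE"),
            )
        )
        assert len(table) == 2

    def test_summary_counts(self):
        table = unique_gene_table(
            self.links(
                ("p1", "g1", 0, 0, True, False, "GAS"),
                ("p2", "g2", 3000, 3000, False, False, "GAS"),
                ("p3", "g3", 0, 0, True, False, "ISRE"),
            )
        )
        summary = link_summary(table)
        assert summary.loc["GAS", "promoter"] == 1
        assert summary.loc["GAS", "distal"] == 1
        assert summary["total"].sum() == 3


class TestDistances:
    def test_all_peaks_at_tss_zero_distances(self):
        a = ann(("g1", "c", 200, "+"))
        links = link_peaks([GenomicInterval("c", 100, 300, name="p")], a, {"g1"})
        dist = distance_distribution(links)
        assert np.allclose(dist["ALL"], 0.0)

    def test_single_peak_distribution_size_one(self):
        a = ann(("g1", "c", 500, "+"))
        links = link_peaks(
            [GenomicInterval("c", 100, 300, name="p")], a, {"g1"}, categories={"p": "GAS"}
        )
        assert len(distance_distribution(links)["GAS"]) == 1

    def test_translation_invariance_of_promoter_flag(self):
        shift = 10_000
        a1 = ann(("g1", "c", 5000, "+"))
        a2 = ann(("g1", "c", 5000 + shift, "+"))
        p1 = GenomicInterval("c", 4500, 4700, name="p")
        p2 = GenomicInterval("c", 4500 + shift, 4700 + shift, name="p")
        l1, l2 = link_peak(p1, a1, {"g1"}), link_peak(p2, a2, {"g1"})
        assert l1["promoter"] == l2["promoter"]
        assert l1["signed_distance"] == l2["signed_distance"]


class TestSyntheticRecovery:
    def test_links_recover_planted_assignments(self, noiseless_small):
        _, ds = noiseless_small
        truth = ds.truth.peaks
        expressed = set(ds.truth.genes.index)
        links = link_peaks(ds.peaks, ds.tss, expressed, categories=truth["category"])
        merged = links.set_index("peak_id")
        assert (merged["gene_id"] == truth.loc[merged.index, "linked_gene"]).all()

    def test_planted_promoter_flags_recovered(self, noiseless_small):
        _, ds = noiseless_small
        truth = ds.truth.peaks
        links = link_peaks(ds.peaks, ds.tss, set(ds.truth.genes.index)).set_index("peak_id")
        assert (links["promoter"] == truth["promoter"]).all()

    def test_gas_planted_farther_gives_larger_median(self):
        # planted placement control: GAS distal-only vs ISRE promoter-only
        from ifnsynergy.synthetic import SimulationParams, simulate_all

        params = SimulationParams(
            seed=21, n_peaks=40, n_genes=240, n_isgs=20,
            chip_noise_sigma=0.0, nb_dispersion=0.0, promoter_frac=0.5,
        )
        ds = simulate_all(params)
        truth = ds.truth.peaks
        links = link_peaks(ds.peaks, ds.tss, set(ds.truth.genes.index),
                           categories=truth["category"])
        # restrict to planted-promoter ISRE vs planted-distal GAS peaks
        distal_gas = truth.index[(truth["category"] == "GAS") & ~truth["promoter"]]
        prom_isre = truth.index[(truth["category"] == "ISRE") & truth["promoter"]]
        sub = links[links["peak_id"].isin(set(distal_gas) | set(prom_isre))]
        med = distance_summary(sub)["median_distance"]
        assert med["GAS"] > med["ISRE"]
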