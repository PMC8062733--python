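"""Generator contracts: motif-free background, planted truth, determinism."""

import numpy as np
import pytest

from ifnsynergy.errors import GenerationError, ValidationError
from ifnsynergy.motifs import count_family_hits
from ifnsynergy.synthetic import (
    DEFAULT_PROPORTIONS,
    SimulationParams,
    allocate_categories,
    simulate_all,
    simulate_genome,
)


def small_params(**kwargs):
    defaults = dict(n_peaks=40, n_genes=240, n_isgs=24, seed=5)
    defaults.update(kwargs)
    return SimulationParams(**defaults)


class TestGenome:
    def test_zero_gc_gives_AT_only(self):
        genome = simulate_genome(small_params(gc_background=0.0))
        for chrom in genome.chroms():
            assert set(genome[chrom]) <= {"A", "T"}

    def test_background_is_motif_free(self):
        genome = simulate_genome(small_params())
        for chrom in genome.chroms():
            assert count_family_hits(genome[chrom]) == (0, 0)

    def test_gc_fraction_concentrates_at_target(self):
        # >= 100 kb per chromosome: GC within +/- 2% of the target
        params = small_params(
            n_peaks=10, n_genes=60, n_isgs=6, n_chroms=1,
            chrom_length=120_000, gc_background=0.5,
        )
        genome = simulate_genome(params)
        seq = genome[genome.chroms()[0]]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_capacity_error_when_chrom_too_small(self):
        with pytest.raises(GenerationError):
            simulate_genome(small_params(chrom_length=10_000))


class TestAllocation:
    def test_printed_category_sizes_at_723(self):
        counts = allocate_categories(723, DEFAULT_PROPORTIONS)
        assert counts == {"GAS": 280, "ISRE": 201, "BOTH": 155, "NO_MOTIF": 87}

    def test_allocation_sums_to_total(self):
        for n in (10, 100, 722, 723, 724):
            counts = allocate_categories(n, DEFAULT_PROPORTIONS)
            assert sum(counts.values()) == n

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SimulationParams(category_proportions={"GAS": 0.5, "ISRE": 0.1})


class TestPeaksAndSignal:
    def test_planted_motifs_lie_inside_their_peaks(self, noiseless_small):
        _, ds = noiseless_small
        t = ds.truth.peaks
        planted = t[t["gas_site_start"] >= 0]
        assert ((planted["gas_site_start"] >= planted["start"]) & (planted["gas_site_end"] <= planted["end"])).all()
        planted = t[t["isre_site_start"] >= 0]
        assert ((planted["isre_site_start"] >= planted["start"]) & (planted["isre_site_end"] <= planted["end"])).all()

    def test_peak_sequences_scan_back_to_their_category(self, noiseless_small):
        _, ds = noiseless_small
        for peak in ds.peaks:
            seq = ds.genome.subsequence(peak.chrom, peak.start, peak.end)
            gas, isre = count_family_hits(seq)
            cat = ds.truth.peaks.loc[peak.name, "category"]
            want = {"GAS": (True, False), "ISRE": (False, True), "BOTH": (True, True), "NO_MOTIF": (False, False)}[cat]
            assert (gas > 0, isre > 0) == want

    def test_noiseless_signal_equals_planted_fold_exactly(self, noiseless_small):
        _, ds = noiseless_small
        t = ds.truth.peaks
        basal = ds.signal["unstim_0U_0h_r1"]
        # high dose, latest timepoint
        col = "beta_10U_4h_r1"
        observed_fold = ds.signal[col] / basal
        planted = ds.truth.peak_folds["dose10_t4"]
        assert np.allclose(observed_fold, planted)

    def test_gas_dose_gate_low_dose_fold_is_one(self, noiseless_small):
        _, ds = noiseless_small
        t = ds.truth.peaks
        gas = t.index[t["category"] == "GAS"]
        low_cols = [c for c in ds.truth.peak_folds.columns if c.startswith("dose1_")]
        assert (ds.truth.peak_folds.loc[gas, low_cols] == 1.0).all().all()

    def test_inducible_flag_follows_planted_folds(self, noiseless_small):
        params, ds = noiseless_small
        folds = ds.truth.peak_folds
        expected = (folds >= params.induction_fold).sum(axis=1) >= params.min_timepoints
        assert (ds.truth.peaks["inducible"] == expected).all()

    def test_same_seed_twice_is_byte_identical(self, tmp_path):
        from ifnsynergy.synthetic import write_dataset

        for sub in ("a", "b"):
            ds = simulate_all(small_params())
            write_dataset(ds, tmp_path / sub)
        for name in ("genome.fa", "peaks.bed", "chip_signal.tsv", "counts.tsv", "truth_genes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestExpression:
    def test_noiseless_synergy_formula(self):
        # s = 2 with beta = gamma = 10 RPKM responses -> mixed mean 40 RPKM
        params = small_params(
            nb_dispersion=0.0,
            chip_noise_sigma=0.0,
            synergy_factor=2.0,
            isg_single_rpkm_range=(10.0, 10.0),
            category_proportions={"BOTH": 1.0, "GAS": 0.0, "ISRE": 0.0, "NO_MOTIF": 0.0},
            frac_inducible=1.0,
            linked_isg_rate=1.0,
        )
        ds = simulate_all(params)
        tg = ds.truth.genes
        syn = tg[(tg["is_isg"]) & (tg["synergy_factor"] == 2.0)]
        assert len(syn) > 0
        assert np.allclose(syn["rpkm_mixed"], 40.0)

    def test_epithelial_mode_gas_linked_genes_flat(self, noiseless_small):
        _, ds = noiseless_small
        tg = ds.truth.genes
        gas_linked = tg[tg["peak_category"] == "GAS"]
        assert not gas_linked["is_isg"].any()
        assert np.allclose(gas_linked["fold_high"], 1.0)

    def test_macrophage_mode_gas_linked_isgs_induced(self):
        params = small_params(cell_mode="macrophage", nb_dispersion=0.0, chip_noise_sigma=0.0)
        ds = simulate_all(params)
        tg = ds.truth.genes
        gas_isgs = tg[(tg["peak_category"] == "GAS") & tg["is_isg"]]
        assert len(gas_isgs) > 0
        assert (gas_isgs["fold_high"] > 2.0).all()

    def test_counts_are_nonnegative_integers(self, noisy_small):
        _, ds = noisy_small
        counts = ds.expression.counts
        assert (counts.to_numpy() >= 0).all()
        assert np.array_equal(counts.to_numpy(), counts.to_numpy().astype(np.int64))

    def test_truth_covers_all_genes_and_peaks(self, noisy_small):
        params, ds = noisy_small
        assert len(ds.truth.peaks) == params.n_peaks
        assert len(ds.truth.genes) == params.n_genes
        assert int(ds.truth.genes["is_isg"].sum()) == params.n_isgs
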