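"""Landscape generation, library/selection simulation, fixture emitters."""

import numpy as np
import pandas as pd
import pytest

from selectome import (
    SelectionConfig,
    cluster_naive,
    cluster_probabilities,
    emit_kinetics_table,
    make_landscape,
    plant_cleavage_sites,
    project_tetramer,
    shannon_entropy,
    simulate_naive_library,
    simulate_selection,
)
from selectome.simulate import (
    decode_peptides,
    encode_peptides,
    hexamer_tetramer_codes,
    hexamer_set_from_codes,
)


class TestLandscape:
    def test_deterministic_per_seed(self):
        a = make_landscape(seed=5)
        b = make_landscape(seed=5)
        assert np.array_equal(a.rates, b.rates)
        assert not np.array_equal(a.rates, make_landscape(seed=6).rates)

    def test_single_peak(self):
        land = make_landscape(seed=1, single_peak=("PANQ", 3289.0))
        assert land.rate_of("PANQ") == 3289.0
        assert np.count_nonzero(land.rates) == 1

    def test_flat_landscape(self):
        land = make_landscape(seed=1, weights=np.zeros((4, 20)), noise_sd=0.0,
                              scale=7.0)
        assert np.all(land.rates == 7.0)

    def test_additive_weights_order_rates(self):
        weights = np.zeros((4, 20))
        weights[0, 0] = 2.0  # residue A at P3
        land = make_landscape(seed=1, weights=weights, noise_sd=0.0, scale=1.0)
        assert land.rate_of("ACDE") == pytest.approx(np.exp(2.0))
        assert land.rate_of("CCDE") == pytest.approx(1.0)


class TestPeptideCodes:
    def test_encode_decode_round_trip(self):
        peps = ["PANQAG", "AAAAAA", "YYYYYY", "KELANQ"]
        assert decode_peptides(encode_peptides(peps, 6), 6) == peps

    def test_tetramer_windows_match_string_slices(self):
        peps = ["PANQAG", "KELANQ", "LPANQA"]
        codes = hexamer_tetramer_codes(encode_peptides(peps, 6))
        for i, pep in enumerate(peps):
            decoded = decode_peptides(codes[i], 4)
            assert decoded == [pep[o : o + 4] for o in range(3)]


class TestNaiveLibrary:
    def test_seed_reproducibility(self):
        a, codes_a, counts_a = simulate_naive_library(5000, 20_000, seed=3)
        b, codes_b, counts_b = simulate_naive_library(5000, 20_000, seed=3)
        assert a.counts == b.counts
        assert np.array_equal(codes_a, codes_b)

    def test_near_uniform_tetramer_entropy(self):
        """A large uniform hexamer library should cluster to within 2% of
        the uniform-tetramer entropy log2(160,000) = 17.288 bits."""
        naive, _, _ = simulate_naive_library(200_000, 600_000, seed=8)
        h = shannon_entropy(cluster_probabilities(cluster_naive(naive)))
        assert h > 0.98 * 17.288
        assert h <= 17.289

    def test_single_hexamer_library(self):
        naive, _, _ = simulate_naive_library(1, 10, seed=4)
        table = cluster_naive(naive)
        assert 1 <= table.n_clusters <= 3


class TestSimulateSelection:
    def _library(self, n=20_000, depth=100_000, seed=13):
        return simulate_naive_library(n, depth, seed)

    def test_reference_substrate_cleaved_99_percent(self):
        """A hexamer with k_eff = 3,289 M^-1 s^-1 at 200 nM for 2 h has a
        0.99 per-round retention probability."""
        p = 1 - np.exp(-3289 * 200e-9 * 7200)
        assert round(p, 2) == 0.99

    def test_cleavage_probability_monotone(self):
        rates = np.array([10.0, 100.0, 1000.0, 10000.0])
        p_rate = 1 - np.exp(-rates * 200e-9 * 7200)
        assert np.all(np.diff(p_rate) > 0)
        for conc in (100e-9, 400e-9):
            assert np.all(
                1 - np.exp(-rates * conc * 7200) <= 1 - np.exp(-rates * 2 * conc * 7200)
            )

    def test_zero_enzyme_keeps_background_only(self):
        _, codes, counts = self._library()
        cfg = SelectionConfig(seed=2, enzyme_conc=0.0, selection_depth=5000,
                              immunodepletion_efficiency=0.9)
        land = make_landscape(seed=2)
        rounds = simulate_selection(codes, counts, land, cfg)
        survivors = rounds[-1][1].sum()
        assert survivors == 5000  # resampled background, no cleavage signal

    def test_seed_determinism(self):
        _, codes, counts = self._library()
        cfg = SelectionConfig(seed=5, selection_depth=5000)
        land = make_landscape(seed=5)
        r1 = simulate_selection(codes, counts, land, cfg)
        r2 = simulate_selection(codes, counts, land, cfg)
        for (c1, n1), (c2, n2) in zip(r1, r2):
            assert np.array_equal(c1, c2) and np.array_equal(n1, n2)

    def test_extinct_pool_is_an_error(self):
        _, codes, counts = self._library(n=50, depth=100)
        cfg = SelectionConfig(seed=1, enzyme_conc=0.0, immunodepletion_efficiency=1.0)
        with pytest.raises(RuntimeError, match="survived"):
            simulate_selection(codes, counts, make_landscape(seed=1), cfg)


class TestKineticsEmitter:
    def test_censoring_at_ceiling(self):
        land = make_landscape(seed=1, single_peak=("PANQ", 1e6), context_sd=0.0)
        df = emit_kinetics_table(land, ["PANQAG"], noise_sd=0.0, ceiling=12_792.0)
        assert df.loc[0, "constant"] == 12_792.0

    def test_zero_rate_tetramer(self):
        land = make_landscape(seed=1, single_peak=("PANQ", 100.0), context_sd=0.0)
        df = emit_kinetics_table(land, ["WWWWWW"], noise_sd=0.0)
        assert df.loc[0, "constant"] == 0.0

    def test_detection_floor_zeroes_weak_substrates(self):
        land = make_landscape(seed=1, single_peak=("PANQ", 30.0), context_sd=0.0)
        df = emit_kinetics_table(land, ["PANQAG"], noise_sd=0.0, floor=50.0)
        assert df.loc[0, "constant"] == 0.0

    def test_noiseless_rates_exact(self):
        land = make_landscape(seed=1, single_peak=("PANQ", 100.0), context_sd=0.0)
        df = emit_kinetics_table(land, ["PANQAG", "LPANQA"], noise_sd=0.0)
        assert df["constant"].tolist() == [100.0, 100.0]
        # P1' index follows the best-site offset
        assert df.loc[0, "cleavage_index"] == 4
        assert df.loc[1, "cleavage_index"] == 5


class TestPlantedSites:
    def test_recorded_positions_round_trip(self):
        land = make_landscape(seed=6)
        proteome, sites = plant_cleavage_sites(land, n_proteins=5, n_sites=12, seed=6)
        for row in sites.itertuples(index=False):
            assert (
                project_tetramer(proteome[row.protein_id], row.p1prime_index)
                == row.true_tetramer
            )

    def test_hot_sites_carry_high_ie(self):
        land = make_landscape(seed=6)
        _, sites = plant_cleavage_sites(land, n_proteins=8, n_sites=40, seed=7)
        hot = sites[sites.true_hot]["ie_log2"]
        cold = sites[~sites.true_hot]["ie_log2"]
        assert hot.mean() > cold.mean() + 1.0
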