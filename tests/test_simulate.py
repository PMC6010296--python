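"""Statistical and determinism checks on the synthetic-data generators."""

import numpy as np
import pytest

from transhic import (
    PipelineConfig,
    Region,
    SimulationSpec,
    simulate_binned_contacts,
    simulate_expression,
    simulate_genes,
    simulate_genome,
    simulate_read_pairs,
)
from transhic.bins import build_bins
from transhic.simulate import ClusterSpec


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        spec = SimulationSpec(seed=1)
        a = simulate_genome(spec)
        b = simulate_genome(spec)
        assert a[0] == b[0]
        for x, y in zip(a[1:], b[1:]):
            assert x.regions == y.regions

    def test_zero_blacklist_fraction_empty_set(self):
        spec = SimulationSpec(seed=2, blacklist_fraction=0.0)
        _, blacklist, _, _ = simulate_genome(spec)
        assert len(blacklist) == 0

    def test_telomeres_are_chromosome_ends(self):
        spec = SimulationSpec(seed=3, telomere_cluster=ClusterSpec(width=250_000))
        layout, _, _, telomere = simulate_genome(spec)
        for name, length in layout.chroms:
            regs = telomere.on(name)
            assert Region(name, 0, 250_000) in regs
            assert Region(name, length - 250_000, length) in regs

    def test_blacklist_coverage_matches_target(self):
        """Mean covered fraction over 100 seeds within 0.05 +/- 0.01
        (merging overlaps pulls realised coverage slightly below nominal)."""
        fractions = []
        for seed in range(100):
            spec = SimulationSpec(seed=seed, n_chroms=1, blacklist_fraction=0.05)
            layout, blacklist, _, _ = simulate_genome(spec)
            fractions.append(blacklist.total_length() / layout.length("chr1"))
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.01)

    def test_annotation_wider_than_chromosome_errors(self):
        spec = SimulationSpec(
            chrom_length=1_000_000, telomere_cluster=ClusterSpec(width=600_000)
        )
        with pytest.raises(ValueError, match="telomere"):
            simulate_genome(spec)


class TestSimulateBinnedContacts:
    def _setup(self, spec):
        layout, blacklist, cen, tel = simulate_genome(spec)
        grid = build_bins(layout, blacklist, 50_000)
        return layout, {"telomere": tel, "centromere": cen}, grid

    def test_all_rates_zero_empty_counts(self):
        spec = SimulationSpec(seed=4, cis_rate=0.0, trans_background_rate=0.0)
        layout, ann, grid = self._setup(spec)
        counts = simulate_binned_contacts(layout, ann, spec, grid)
        assert counts.n_entries == 0

    def test_deterministic_given_seed(self):
        spec = SimulationSpec(seed=5, chrom_length=2_000_000)
        layout, ann, grid = self._setup(spec)
        c1 = simulate_binned_contacts(layout, ann, spec, grid)
        c2 = simulate_binned_contacts(layout, ann, spec, grid)
        assert np.array_equal(c1.counts, c2.counts)

    def test_canonical_order_and_uniqueness(self):
        spec = SimulationSpec(seed=6, chrom_length=2_000_000)
        layout, ann, grid = self._setup(spec)
        counts = simulate_binned_contacts(layout, ann, spec, grid)
        assert np.all(counts.bin1 <= counts.bin2)

    def test_trans_background_mean_matches_rate(self):
        """Empirical trans mean within 3 standard errors of lambda."""
        lam = 1.0
        total = 0.0
        n_draws = 0
        for seed in range(30):
            spec = SimulationSpec(
                seed=seed,
                chrom_length=2_000_000,
                cis_rate=0.0,
                trans_background_rate=lam,
                blacklist_fraction=0.0,
            )
            layout, ann, grid = self._setup(spec)
            counts = simulate_binned_contacts(layout, ann, spec, grid)
            n1, n2 = grid.n_bins("chr1"), grid.n_bins("chr2")
            total += counts.total()
            n_draws += n1 * n2 * spec.n_libraries
        se = np.sqrt(lam / n_draws)
        assert total / n_draws == pytest.approx(lam, abs=3 * se)

    def test_planted_loop_fold_reflected_in_mean(self):
        """A fold-20 trans loop's empirical mean is ~20 lambda."""
        lam, fold = 1.0, 20.0
        vals = []
        for seed in range(100):
            spec = SimulationSpec(
                seed=seed,
                chrom_length=2_000_000,
                cis_rate=0.0,
                trans_background_rate=lam,
                blacklist_fraction=0.0,
            )
            layout, ann, grid = self._setup(spec)
            # plant on one exact grid bin pair
            b1 = grid.bins[grid.bin_id("chr1", 1_000_000)]
            b2 = grid.bins[grid.bin_id("chr2", 1_000_000)]
            spec.planted_loops = [(b1, b2, fold)]
            counts = simulate_binned_contacts(layout, ann, spec, grid)
            i1, i2 = grid.bin_id("chr1", 1_000_000), grid.bin_id("chr2", 1_000_000)
            sel = (counts.bin1 == i1) & (counts.bin2 == i2)
            vals.extend(counts.counts[sel].ravel().tolist())
        se = np.sqrt(fold * lam / len(vals))
        assert np.mean(vals) == pytest.approx(fold * lam, abs=3 * se)

    def test_telomere_clustering_boosts_end_pairs(self):
        spec = SimulationSpec(
            seed=8,
            chrom_length=5_000_000,
            cis_rate=0.0,
            trans_background_rate=1.0,
            telomere_cluster=ClusterSpec(width=500_000, fold=10.0),
            blacklist_fraction=0.0,
        )
        layout, ann, grid = self._setup(spec)
        counts = simulate_binned_contacts(layout, ann, spec, grid)
        tel_start = {c: 500_000 for c in layout.names}
        in_tel = np.zeros(counts.n_entries, dtype=bool)
        for k in range(counts.n_entries):
            a = grid.bins[int(counts.bin1[k])]
            b = grid.bins[int(counts.bin2[k])]
            def near_end(r):
                L = layout.length(r.chrom)
                return r.midpoint < tel_start[r.chrom] or r.midpoint > L - tel_start[r.chrom]
            in_tel[k] = near_end(a) and near_end(b)
        mean_tel = counts.mean_counts()[in_tel].mean()
        mean_bg = counts.mean_counts()[~in_tel].mean()
        assert mean_tel > 5 * mean_bg

    def test_library_streams_stable_under_n_libraries(self):
        """Adding a library never changes counts drawn for earlier ones."""
        spec2 = SimulationSpec(seed=9, chrom_length=2_000_000, n_libraries=2)
        spec3 = SimulationSpec(seed=9, chrom_length=2_000_000, n_libraries=3)
        layout, ann, grid = self._setup(spec2)
        c2 = simulate_binned_contacts(layout, ann, spec2, grid)
        c3 = simulate_binned_contacts(layout, ann, spec3, grid)
        # compare dense projections of the first two libraries
        d2 = {(int(a), int(b)): tuple(row[:2]) for a, b, row in zip(c2.bin1, c2.bin2, c2.counts)}
        d3 = {(int(a), int(b)): tuple(row[:2]) for a, b, row in zip(c3.bin1, c3.bin2, c3.counts)}
        for key in set(d2) | set(d3):
            assert d2.get(key, (0, 0)) == d3.get(key, (0, 0))


class TestSimulateReadPairs:
    def test_deterministic(self, toy_layout):
        spec = SimulationSpec(seed=10, n_read_pairs=300)
        r1, l1 = simulate_read_pairs(toy_layout, spec)
        r2, l2 = simulate_read_pairs(toy_layout, spec)
        assert r1 == r2 and l1 == l2

    def test_fraction_validation(self, toy_layout):
        from transhic.simulate import ArtifactFractions

        spec = SimulationSpec(
            artifact_fractions=ArtifactFractions(0.5, 0.3, 0.3, 0, 0, 0)
        )
        with pytest.raises(ValueError, match="sum"):
            simulate_read_pairs(toy_layout, spec)


class TestSimulateExpression:
    @pytest.fixture
    def setup(self):
        spec = SimulationSpec(seed=11)
        layout, *_ = simulate_genome(spec)
        genes = simulate_genes(layout, n_genes=5, seed=11)
        return layout, genes

    def test_zero_base_zero_everywhere_no_flags(self, setup):
        layout, genes = setup
        table = simulate_expression(
            layout, genes, ["B", "T"], {"gene0": (0.0, ("B", 8.0))}, seed=1
        )
        row = table[table.gene_id == "gene0"].iloc[0]
        assert row["rpkm_B"] == 0.0 and row["rpkm_T"] == 0.0
        assert not row["de_B"] and not row["de_T"]

    def test_de_effect_mean_matches_fold(self, setup):
        """Base 2, fold 8 in B -> B-lineage mean RPKM ~ 16 over 100 seeds."""
        layout, genes = setup
        sigma = 0.25
        vals = []
        for seed in range(100):
            t = simulate_expression(
                layout, genes, ["B", "T"], {"gene1": (2.0, ("B", 8.0))}, seed=seed,
                sigma=sigma,
            )
            vals.append(float(t[t.gene_id == "gene1"].iloc[0]["rpkm_B"]))
        se = 16.0 * sigma / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(16.0, abs=3 * se)

    def test_de_flag_exactly_where_effect_given(self, setup):
        layout, genes = setup
        t = simulate_expression(
            layout, genes, ["B", "T"],
            {"gene0": (2.0, ("B", 4.0)), "gene1": (3.0, None)}, seed=2,
        )
        assert t.set_index("gene_id").loc["gene0", "de_B"]
        assert not t.set_index("gene_id").loc["gene0", "de_T"]
        assert not t.set_index("gene_id").loc["gene1", "de_B"]

    def test_unknown_lineage_errors(self, setup):
        layout, genes = setup
        with pytest.raises(ValueError, match="NK"):
            simulate_expression(layout, genes, ["B"], {"gene0": (1.0, ("NK", 2.0))})

    def test_same_seed_identical_table(self, setup):
        layout, genes = setup
        spec = {"gene0": (2.0, ("B", 4.0))}
        t1 = simulate_expression(layout, genes, ["B", "T"], spec, seed=3)
        t2 = simulate_expression(layout, genes, ["B", "T"], spec, seed=3)
        assert t1.equals(t2)
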