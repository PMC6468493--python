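"""Synthetic-data generator contracts: determinism, planted-site census,
proper-pair construction, ChIP enrichment, Ct shifts."""

import numpy as np
import pytest
from scipy import stats

from divanet import profile3p, simulate
from divanet.simulate import SimTruth, simulate_chip, simulate_ct, simulate_genome, simulate_mnet

from conftest import brute_force_scan, sam_to_text


class TestSimulateGenome:
    def test_single_site_found_by_brute_force(self):
        genome, truth, _ = simulate_genome(
            n_chrom=1, length_bp=10_000, n_sites=1, n_genes=1, seed=7
        )
        assert brute_force_scan(genome) == sorted(truth.site_positions)
        assert len(truth.site_positions) == 1

    def test_identical_seed_identical_output(self):
        a = simulate_genome(n_chrom=2, length_bp=40_000, n_sites=4, n_genes=6, seed=7)
        b = simulate_genome(n_chrom=2, length_bp=40_000, n_sites=4, n_genes=6, seed=7)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].equals(b[2])

    def test_different_seed_different_sequence(self):
        a = simulate_genome(length_bp=20_000, n_sites=1, n_genes=2, seed=1)
        b = simulate_genome(length_bp=20_000, n_sites=1, n_genes=2, seed=2)
        assert a[0] != b[0]

    def test_packing_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(n_chrom=1, length_bp=20_000, n_sites=10, n_genes=10, seed=0)

    def test_census_is_exact_even_at_megabase_scale(self):
        """Spontaneous occurrences are destroyed: the planted set is the
        full census (expected ~15 spontaneous 8-mers per Mb before cleanup)."""
        genome, truth, _ = simulate_genome(
            n_chrom=1, length_bp=1_000_000, n_sites=30, n_genes=40, seed=3
        )
        assert brute_force_scan(genome) == sorted(truth.site_positions)

    def test_sites_respect_flank_margin_and_do_not_overlap(self):
        _, truth, _ = simulate_genome(
            n_chrom=2, length_bp=60_000, n_sites=10, n_genes=12, seed=5
        )
        by_chrom = {}
        for chrom, start in truth.site_positions:
            assert truth.flank <= start <= truth.chrom_lengths[chrom] - truth.flank - 8
            by_chrom.setdefault(chrom, []).append(start)
        for starts in by_chrom.values():
            starts.sort()
            assert all(b - a >= 8 for a, b in zip(starts, starts[1:]))

    def test_genes_nonoverlapping_and_contain_their_sites(self):
        genome, truth, genes = simulate_genome(
            n_chrom=1, length_bp=100_000, n_sites=8, n_genes=10, seed=9
        )
        g = genes.sort_values("start")
        assert (g["start"].values[1:] >= g["end"].values[:-1]).all()
        for (chrom, start), genic in zip(truth.site_positions, truth.site_genic):
            inside = (
                (genes["chrom"] == chrom)
                & (genes["start"] <= start)
                & (genes["end"] >= start + 8)
            ).any()
            assert inside == genic

    def test_intergenic_sites_are_uncut_and_outside_genes(self):
        genome, truth, genes = simulate_genome(
            n_chrom=1, length_bp=100_000, n_sites=5, n_genes=6, seed=2, n_intergenic=3
        )
        assert truth.site_genic.count(False) == 3
        for (chrom, start), genic, cut in zip(
            truth.site_positions, truth.site_genic, truth.cut_flags
        ):
            if not genic:
                assert not cut
        assert brute_force_scan(genome) == sorted(truth.site_positions)

    def test_cut_fraction_zero_for_uncut(self):
        _, truth, _ = simulate_genome(length_bp=100_000, n_sites=10, n_genes=12, seed=4)
        for cut, f in zip(truth.cut_flags, truth.cut_fraction):
            assert (f > 0) == cut


class TestSimTruthInvariants:
    def test_rejects_site_in_flank(self):
        with pytest.raises(ValueError, match="flank"):
            SimTruth(
                seed=0, chrom_lengths={"chr1": 10_000},
                site_positions=[("chr1", 100)], cut_flags=[True], cut_fraction=[0.5],
            )

    def test_rejects_overlapping_sites(self):
        with pytest.raises(ValueError, match="overlap"):
            SimTruth(
                seed=0, chrom_lengths={"chr1": 10_000},
                site_positions=[("chr1", 3000), ("chr1", 3004)],
                cut_flags=[True, True], cut_fraction=[0.5, 0.5],
            )

    def test_rejects_nonzero_fraction_at_uncut_site(self):
        with pytest.raises(ValueError, match="uncut"):
            SimTruth(
                seed=0, chrom_lengths={"chr1": 10_000},
                site_positions=[("chr1", 3000)], cut_flags=[False], cut_fraction=[0.2],
            )

    def test_json_round_trip(self, small_sim):
        _, truth, _ = small_sim
        assert SimTruth.from_json(truth.to_json()) == truth


class TestSimulateMnet:
    def test_all_flag_pairs_proper(self, small_sim):
        genome, truth, genes = small_sim
        records, _ = simulate_mnet(genome, truth, genes, induced=True, seed=0)
        flags = {}
        for r in records:
            flags.setdefault(r.query_name, []).append(r.flag)
        for pair in flags.values():
            r1 = next(f for f in pair if f & 0x40)
            r2 = next(f for f in pair if f & 0x80)
            assert (r1, r2) in {(99, 147), (83, 163)}

    def test_mate_fields_consistent(self, small_sim):
        genome, truth, genes = small_sim
        records, _ = simulate_mnet(genome, truth, genes, induced=False, seed=0)
        by_name = {}
        for r in records:
            by_name.setdefault(r.query_name, []).append(r)
        for r1, r2 in by_name.values():
            assert r1.next_reference_start == r2.reference_start
            assert r2.next_reference_start == r1.reference_start
            assert r1.template_length == -r2.template_length
            assert abs(r1.template_length) == truth.insert_size

    def test_records_valid_sam(self, small_sim, tmp_path):
        import pysam

        genome, truth, genes = small_sim
        records, header = simulate_mnet(genome, truth, genes, induced=True, seed=1)
        path = tmp_path / "sim.sam"
        simulate.write_sam(records, header, path)
        with pysam.AlignmentFile(str(path)) as fh:
            n = sum(1 for _ in fh)
        assert n == len(records)

    def test_uninduced_has_no_site_proximal_excess(self):
        """Without induction, counts near sites are uniform over the gene
        body: chi-square of near-site vs elsewhere bins not significant."""
        genome, truth, genes = simulate_genome(
            n_chrom=1, length_bp=400_000, n_sites=20, n_genes=40, seed=21,
            background_rate=50.0,
        )
        records, _ = simulate_mnet(genome, truth, genes, induced=False, seed=22)
        profile = profile3p.build_profile(records)
        site_pos = {s for _, s in truth.site_positions}
        # per gene with a site: compare counts within +-500 bp of the site
        # to the uniform expectation over the gene body
        chisq, dof = 0.0, 0
        for row in genes.itertuples(index=False):
            hits = [s for s in site_pos if row.start <= s < row.end]
            if not hits:
                continue
            total = sum(
                profile.get("chr1", p, st)
                for st in "+-"
                for p in range(row.start, row.end)
            )
            if total < 20:
                continue
            near = sum(
                profile.get("chr1", p, st)
                for st in "+-"
                for p in range(max(row.start, hits[0] - 500), min(row.end, hits[0] + 500))
            )
            width = min(row.end, hits[0] + 500) - max(row.start, hits[0] - 500)
            expect = total * width / (row.end - row.start)
            chisq += (near - expect) ** 2 / expect + (
                (total - near) - (total - expect)
            ) ** 2 / (total - expect)
            dof += 1
        p = stats.chi2.sf(chisq, dof)
        assert p > 0.01

    def test_induced_reads_near_cut_site_in_most_seeds(self):
        """One cut site, induction 500, no background: a read lands on each
        strand within decay_length of the site in >99% of seeds."""
        genome, truth, genes = simulate_genome(
            n_chrom=1, length_bp=20_000, n_sites=1, n_genes=1, seed=30,
            frac_cut=1.0, cut_fraction=0.8, induction_rate=500.0, background_rate=0.0,
        )
        chrom, site = truth.site_positions[0]
        ok = 0
        for seed in range(100):
            records, _ = simulate_mnet(genome, truth, genes, induced=True, seed=seed)
            profile = profile3p.build_profile(records)
            near = {
                st: sum(
                    profile.get(chrom, p, st)
                    for p in range(site - int(truth.decay_length), site + int(truth.decay_length) + 1)
                )
                for st in "+-"
            }
            ok += near["+"] >= 1 and near["-"] >= 1
        assert ok >= 99

    def test_deterministic(self, small_sim):
        genome, truth, genes = small_sim
        a, header = simulate_mnet(genome, truth, genes, induced=True, seed=5)
        b, _ = simulate_mnet(genome, truth, genes, induced=True, seed=5)
        assert sam_to_text(a, header) == sam_to_text(b, header)


class TestSimulateChip:
    def test_unit_enrichment_means_equal(self):
        _, truth, _ = simulate_genome(
            length_bp=200_000, n_sites=10, n_genes=12, seed=40, chip_enrichment=1.0
        )
        t, c = simulate_chip(truth, depth=200, seed=41)
        assert np.isclose(
            t.values["chr1"].mean(), c.values["chr1"].mean(), rtol=0.02
        )

    def test_window_ratio_converges_to_enrichment(self):
        _, truth, _ = simulate_genome(
            length_bp=200_000, n_sites=4, n_genes=6, seed=42,
            frac_cut=0.5, chip_enrichment=8.0,
        )
        t, c = simulate_chip(truth, depth=2000, seed=43)
        for (chrom, start), cut in zip(truth.site_positions, truth.cut_flags):
            lo, hi = start - truth.chip_spread, start + 8 + truth.chip_spread
            ratio = t.mean(chrom, lo, hi) / c.mean(chrom, lo, hi)
            assert ratio == pytest.approx(8.0 if cut else 1.0, rel=0.05)

    def test_depth_must_be_positive(self, small_sim):
        _, truth, _ = small_sim
        with pytest.raises(ValueError):
            simulate_chip(truth, depth=0, seed=0)

    def test_bedgraph_round_trip(self, small_sim, tmp_path):
        from divanet.tracks import CoverageTrack

        _, truth, _ = small_sim
        t, _ = simulate_chip(truth, depth=20, seed=44)
        path = tmp_path / "t.bedgraph"
        t.to_bedgraph(path)
        back = CoverageTrack.from_bedgraph(path, t.binsize, truth.chrom_lengths)
        for chrom in t.values:
            np.testing.assert_allclose(back.values[chrom], t.values[chrom])


class TestSimulateCt:
    def _truth(self, f):
        return SimTruth(
            seed=0, chrom_lengths={"chr1": 20_000},
            site_positions=[("chr1", 5000)], cut_flags=[f > 0], cut_fraction=[f],
            ct_noise_sd=0.0,
        )

    @pytest.mark.parametrize("f,shift", [(0.5, 1.0), (0.75, 2.0), (0.0, 0.0)])
    def test_noise_free_ct_shift(self, f, shift):
        table = simulate_ct(self._truth(f), {"amp": 0}, replicates=2, seed=1)
        amp = table[table.amplicon_id == "amp"]
        treated = amp[amp.condition == "treated"]["ct"].mean()
        untreated = amp[amp.condition == "untreated"]["ct"].mean()
        assert treated - untreated == pytest.approx(shift)

    def test_housekeeping_and_control_have_no_shift(self):
        table = simulate_ct(self._truth(0.5), {"amp": 0}, replicates=3, seed=2)
        for amp in ("ACTB", "GAPDH", "noDSB"):
            sub = table[table.amplicon_id == amp]
            assert (
                sub[sub.condition == "treated"]["ct"].mean()
                == pytest.approx(sub[sub.condition == "untreated"]["ct"].mean())
            )

    def test_baseline_in_range(self):
        table = simulate_ct(self._truth(0.0), {"amp": 0}, replicates=1, seed=3)
        untreated = table[table.condition == "untreated"]
        assert ((untreated["ct"] >= 18) & (untreated["ct"] <= 26)).all()

    def test_full_cut_fraction_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            simulate_ct(self._truth(1.0), {"amp": 0}, replicates=1, seed=0)

    def test_replicates_required(self):
        with pytest.raises(ValueError):
            simulate_ct(self._truth(0.5), {"amp": 0}, replicates=0, seed=0)
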