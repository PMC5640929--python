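import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from erparrange.io import ContigSeq, read_contigs
from erparrange.simulate import (
    DepthSpec, FragmentationSpec, GenomeSpec, TruthTable, apply_inversion,
    copy_number_profile, fragment_genome, make_dataset, project_depth,
    simulate_dataset, simulate_depth, simulate_genome,
)


class TestSimulateGenome:
    def test_seeded_determinism(self):
        spec = GenomeSpec(length=100_000, gc=0.43, seed=7)
        assert simulate_genome(spec).sequence == simulate_genome(spec).sequence

    def test_different_seeds_differ(self):
        a = simulate_genome(GenomeSpec(length=10_000, seed=1))
        b = simulate_genome(GenomeSpec(length=10_000, seed=2))
        assert a.sequence != b.sequence

    def test_gc_boundary_all_gc(self):
        seq = simulate_genome(GenomeSpec(length=2000, gc=1.0, seed=3)).sequence
        assert set(seq) <= {"G", "C"}

    def test_gc_fraction_approximate(self):
        seq = simulate_genome(GenomeSpec(length=50_000, gc=0.3, seed=4)).sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.3, abs=0.02)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(length=500)


class TestCopyNumberProfile:
    def test_flat_at_ratio_one(self):
        n = copy_number_profile(GenomeSpec(length=10_000, copy_ratio=1.0))
        assert np.all(n == 1.0)

    def test_symmetric_arm_midpoint_closed_form(self):
        spec = GenomeSpec(length=4_000_000, ori=0, ter=2_000_000, copy_ratio=2.0)
        n = copy_number_profile(spec)
        assert n[1_000_000] == pytest.approx(2 ** 0.5)
        assert n[0] == pytest.approx(2.0)
        assert n[2_000_000] == pytest.approx(1.0)

    def test_asymmetric_arms_have_3x_log_slope(self):
        spec = GenomeSpec(length=4_000_000, ori=0, ter=1_000_000, copy_ratio=2.0)
        n = np.log(copy_number_profile(spec))
        left = abs(n[1] - n[0])       # short arm, 1 Mb
        right = abs(n[-1] - n[-2])    # long arm, 3 Mb
        assert left / right == pytest.approx(3.0, rel=1e-6)

    @given(
        r=st.floats(1.0, 3.0),
        ter_frac=st.floats(0.2, 0.8),
        shape=st.sampled_from(["exponential", "linear"]),
    )
    def test_bounds_and_extremes(self, r, ter_frac, shape):
        L = 10_000
        spec = GenomeSpec(length=L, ori=0, ter=int(ter_frac * L), copy_ratio=r,
                          shape=shape)
        n = copy_number_profile(spec)
        assert np.all((n >= 1.0 - 1e-12) & (n <= r + 1e-12))
        assert n.max() == pytest.approx(r)
        assert n.min() == pytest.approx(1.0)

    def test_default_ratio_keeps_max_coverage_difference_below_threefold(self):
        assert GenomeSpec().copy_ratio <= 3.0


class TestSimulateDepth:
    def test_noiseless_depth_at_origin(self):
        spec = GenomeSpec(length=10_000, copy_ratio=2.0)
        depth = simulate_depth(copy_number_profile(spec), DepthSpec(noise="none"))
        assert depth[0] == pytest.approx(200.0)

    def test_poisson_mean_by_clt(self):
        depth = simulate_depth(np.ones(10_000),
                               DepthSpec(depth_at_ter=100, noise="poisson", seed=5))
        assert abs(depth.mean() - 100.0) < 3.0

    def test_seeded_determinism(self):
        prof = np.ones(1000) * 1.5
        d1 = simulate_depth(prof, DepthSpec(noise="poisson", seed=9))
        d2 = simulate_depth(prof, DepthSpec(noise="poisson", seed=9))
        assert np.array_equal(d1, d2)


class TestFragmentGenome:
    def test_single_contig_is_whole_genome(self):
        genome = simulate_genome(GenomeSpec(length=5000, seed=1))
        contigs, truth = fragment_genome(
            genome, FragmentationSpec(n_contigs=1, min_len=1000,
                                      random_orientation=False)
        )
        assert len(contigs) == 1
        assert contigs[0].sequence == genome.sequence
        assert truth.entries[0].strand == "+"
        truth.validate_tiling()

    def test_tiling_and_min_len(self):
        genome = simulate_genome(GenomeSpec(length=200_000, seed=2))
        fspec = FragmentationSpec(n_contigs=12, min_len=10_000, seed=3)
        contigs, truth = fragment_genome(genome, fspec)
        truth.validate_tiling()
        assert all(c.length >= 10_000 for c in contigs)
        assert sum(c.length for c in contigs) == 200_000

    def test_seeded_determinism(self):
        genome = simulate_genome(GenomeSpec(length=50_000, seed=4))
        fspec = FragmentationSpec(n_contigs=6, min_len=2000, seed=5)
        a, _ = fragment_genome(genome, fspec)
        b, _ = fragment_genome(genome, fspec)
        assert a == b

    def test_cut_sites_become_boundaries(self):
        genome = simulate_genome(GenomeSpec(length=100_000, seed=6))
        fspec = FragmentationSpec(n_contigs=8, min_len=3000, seed=7,
                                  cut_sites=(50_000,))
        _, truth = fragment_genome(genome, fspec)
        assert 50_000 in {e.start for e in truth.entries}

    def test_infeasible_min_len_rejected(self):
        genome = simulate_genome(GenomeSpec(length=10_000, seed=8))
        with pytest.raises(ValueError):
            fragment_genome(genome, FragmentationSpec(n_contigs=20, min_len=1000))

    def test_sequences_match_truth_coordinates(self):
        from erparrange.io import reverse_complement

        gspec = GenomeSpec(length=30_000, seed=9)
        genome = simulate_genome(gspec)
        contigs, truth = fragment_genome(
            genome, FragmentationSpec(n_contigs=5, min_len=2000, seed=10)
        )
        doubled = genome.sequence * 2
        by_id = {c.id: c for c in contigs}
        for e in truth.entries:
            expect = doubled[e.start:e.end]
            if e.strand == "-":
                expect = reverse_complement(expect)
            assert by_id[e.contig_id].sequence == expect


class TestProjectDepth:
    def test_total_depth_is_conserved(self):
        gspec = GenomeSpec(length=50_000, copy_ratio=2.0, seed=11)
        depth = simulate_depth(copy_number_profile(gspec), DepthSpec(noise="none"))
        genome = simulate_genome(gspec)
        _, truth = fragment_genome(genome,
                                   FragmentationSpec(n_contigs=7, min_len=2000,
                                                     seed=12))
        per_contig = project_depth(depth, truth)
        assert sum(v.sum() for v in per_contig.values()) == pytest.approx(depth.sum())

    def test_reverse_strand_vector_is_reversed(self):
        from erparrange.simulate import TruthEntry

        depth = np.arange(100, dtype=float)
        truth = TruthTable(
            entries=[TruthEntry("a", 0, 40, "+", 0),
                     TruthEntry("b", 40, 100, "-", 1)],
            genome_length=100, ori=0, ter=50,
        )
        per = project_depth(depth, truth)
        assert per["a"].tolist() == list(range(40))
        assert per["b"].tolist() == list(range(99, 39, -1))


class TestApplyInversion:
    def test_hand_checked_segment(self):
        genome = ContigSeq("g", "AAACGTTT")
        assert apply_inversion(genome, 1, 5).sequence == "ACGTTTTT"

    def test_whole_genome_inversion_is_reverse_complement(self):
        from erparrange.io import reverse_complement

        genome = simulate_genome(GenomeSpec(length=2000, seed=13))
        inv = apply_inversion(genome, 0, 2000)
        assert inv.sequence == reverse_complement(genome.sequence)

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_double_application_is_identity(self, a, b):
        genome = simulate_genome(GenomeSpec(length=1000, seed=14))
        lo, hi = min(a, b), max(a, b) + 1
        twice = apply_inversion(apply_inversion(genome, lo, hi), lo, hi)
        assert twice.sequence == genome.sequence

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_inversion(ContigSeq("g", "ACGT"), 2, 9)


class TestMakeDataset:
    def test_writes_self_consistent_files(self, tmp_path):
        gspec = GenomeSpec(length=50_000, copy_ratio=2.0, seed=15)
        dspec = DepthSpec(depth_at_ter=50, noise="poisson", seed=16)
        fspec = FragmentationSpec(n_contigs=6, min_len=2000, seed=17)
        paths = make_dataset(gspec, dspec, fspec, tmp_path / "ds")
        assert all(p.exists() for p in paths.values())
        genome = read_contigs(paths["genome"])[0]
        contigs = read_contigs(paths["contigs"])
        assert genome.length == 50_000
        assert sum(c.length for c in contigs) == 50_000
        truth = TruthTable.read_tsv(paths["truth"])
        truth.validate_tiling()
        params = json.loads(paths["params"].read_text())
        assert params["genome"]["length"] == 50_000

    def test_truth_roundtrip(self, tmp_path):
        ds = simulate_dataset(
            GenomeSpec(length=20_000, seed=18),
            DepthSpec(noise="none"),
            FragmentationSpec(n_contigs=4, min_len=2000, seed=19),
        )
        path = tmp_path / "truth.tsv"
        ds.truth.write_tsv(path)
        back = TruthTable.read_tsv(path)
        assert back.entries == ds.truth.entries
        assert (back.genome_length, back.ori, back.ter) == (
            ds.truth.genome_length, ds.truth.ori, ds.truth.ter,
        )
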