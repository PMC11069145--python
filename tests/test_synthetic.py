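import numpy as np
import pytest

from mitoresolve.codon_usage import compute_gc
from mitoresolve.synthetic import (
    ConfigError,
    EditPlant,
    GenePlant,
    MTPTPlant,
    SimulationConfig,
    SSRPlant,
    simulate_cp_with_mtpt,
    simulate_hifi_reads,
    simulate_mitogenome,
    simulate_rna_reads,
)
from .conftest import light_config


class TestGenomeConstruction:
    def test_length_is_forced_by_construction(self, default_dataset):
        config, genome, graph, _, _ = default_dataset
        s = config.seg_lengths
        assert len(genome.seq) == s["ctg1"] + s["ctg2"] + 2 * s["repeat"]
        assert sorted(graph.segment_lengths().values()) == sorted(
            [s["ctg1"], s["ctg2"], s["repeat"]]
        )

    def test_published_scale_arithmetic(self):
        # a 5,596 bp repeat and a 433,466 bp target force the single-copy
        # total to 422,274 bp
        total, repeat = 433_466, 5_596
        single_copy = total - 2 * repeat
        assert single_copy == 422_274
        config = light_config(
            0,
            seg_lengths={
                "ctg1": single_copy // 2 + single_copy % 2,
                "ctg2": single_copy // 2,
                "repeat": repeat,
            },
        )
        assert config.genome_length == total

    def test_same_seed_is_byte_identical(self):
        g1, _, _, _ = simulate_mitogenome(SimulationConfig(seed=33))
        g2, _, _, _ = simulate_mitogenome(SimulationConfig(seed=33))
        assert g1.seq == g2.seq

    def test_different_seed_differs(self):
        g1, _, _, _ = simulate_mitogenome(light_config(1))
        g2, _, _, _ = simulate_mitogenome(light_config(2))
        assert g1.seq != g2.seq

    def test_repeat_occurs_twice_identically(self, default_dataset):
        config, genome, graph, _, _ = default_dataset
        L1 = config.seg_lengths["ctg1"]
        Lr = config.seg_lengths["repeat"]
        L2 = config.seg_lengths["ctg2"]
        occ1 = genome.seq[L1 : L1 + Lr]
        occ2 = genome.seq[L1 + Lr + L2 : L1 + 2 * Lr + L2]
        assert occ1 == occ2 == graph.segments["repeat"]

    def test_gc_target_is_met_on_large_genome(self):
        config = light_config(
            7, seg_lengths={"ctg1": 60000, "ctg2": 50000, "repeat": 5000}
        )
        genome, _, _, _ = simulate_mitogenome(config)
        assert abs(compute_gc(genome.seq) - 0.45) < 0.005

    def test_planted_pcgs_have_valid_orfs(self, default_dataset):
        _, genome, _, annotations, _ = default_dataset
        for ann in annotations:
            if ann.feature_type != "PCG":
                continue
            cds = ann.spliced(genome.seq)
            assert len(cds) % 3 == 0
            assert cds[:3] in ("ATG", "ACG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            internal = {cds[i : i + 3] for i in range(3, len(cds) - 3, 3)}
            assert not internal & {"TAA", "TAG", "TGA"}

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ConfigError):
            simulate_mitogenome(
                SimulationConfig(
                    genes=(
                        GenePlant("a", "PCG", "+", "ctg1", 1000, (300,)),
                        GenePlant("b", "PCG", "+", "ctg1", 1100, (300,)),
                    )
                )
            )

    def test_out_of_bounds_plant_rejected(self):
        with pytest.raises(ConfigError):
            simulate_mitogenome(
                light_config(0, ssrs=(SSRPlant("T", 12, "ctg1", 23_995),))
            )


class TestHifiReads:
    def test_zero_reads_is_not_an_error(self, default_dataset):
        config, genome, _, _, truth = default_dataset
        cfg = SimulationConfig(seed=config.seed, read_count=0)
        reads, support = simulate_hifi_reads(genome, cfg, truth.junction_positions)
        assert reads == []
        assert all(v == 0 for v in support.values())

    def test_reads_too_short_to_span_flanks_support_nothing(self):
        config = light_config(
            5, read_length_mean=300.0, read_length_sd=1.0, read_min_length=100,
            read_count=60,
        )
        genome, _, _, truth = simulate_mitogenome(config)
        _, support = simulate_hifi_reads(genome, config, truth.junction_positions)
        # every read is shorter than twice the junction flank
        assert all(v == 0 for v in support.values())

    def test_truth_support_matches_independent_interval_count(self):
        """Re-derive junction support by locating each error-free read."""
        config = light_config(9, read_error_rate=0.0, read_count=120)
        genome, _, _, truth = simulate_mitogenome(config)
        reads, support = simulate_hifi_reads(genome, config, truth.junction_positions)
        L = len(genome.seq)
        doubled = genome.seq + genome.seq
        recount = {label: 0 for label in truth.junction_positions}
        for read in reads:
            for seq in (read.seq, _rc(read.seq)):
                start = doubled.find(seq)
                if start != -1:
                    break
            assert start != -1, "error-free read must locate in the genome"
            for label, p in truth.junction_positions.items():
                d = (p - start) % L
                if config.min_flank <= d <= len(seq) - config.min_flank:
                    recount[label] += 1
        assert recount == support


def _rc(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestCpWithMtpt:
    def test_exact_fragment_has_exact_truth(self):
        config = light_config(3, mtpts=(MTPTPlant(1000, 1.0, "ctg1", 2000, 5000),))
        genome, _, _, _ = simulate_mitogenome(config)
        cp, _, truths = simulate_cp_with_mtpt(genome, config)
        (t,) = truths
        assert (t.mt_start, t.mt_end, t.cp_start, t.cp_end) == (2001, 3000, 5001, 6000)
        assert genome.seq[2000:3000] == cp.seq[5000:6000]

    def test_hamming_distance_equals_planted_mutations(self):
        config = light_config(4, mtpts=(MTPTPlant(2000, 0.95, "ctg1", 2000, 5000),))
        genome, _, _, _ = simulate_mitogenome(config)
        cp, _, truths = simulate_cp_with_mtpt(genome, config)
        (t,) = truths
        mt = genome.seq[t.mt_start - 1 : t.mt_end]
        cpf = cp.seq[t.cp_start - 1 : t.cp_end]
        hamming = sum(a != b for a, b in zip(mt, cpf))
        assert hamming == t.n_mutations == round(0.05 * 2000)

    def test_shortest_observed_transfer_scale_appears_in_truth(self, default_dataset):
        config, genome, _, _, _ = default_dataset
        _, _, truths = simulate_cp_with_mtpt(genome, config)
        assert min(t.mt_end - t.mt_start + 1 for t in truths) == 29

    def test_low_identity_rejected(self):
        with pytest.raises(ConfigError):
            simulate_mitogenome(
                light_config(0, mtpts=(MTPTPlant(500, 0.5, "ctg1", 2000, 5000),))
            )


class TestRnaReads:
    def test_zero_depth_gives_empty_output(self, default_dataset):
        config, genome, _, annotations, _ = default_dataset
        cfg = SimulationConfig(seed=config.seed, rna_depth=0)
        reads, _ = simulate_rna_reads(annotations, genome, cfg)
        assert reads == []

    def test_full_frequency_site_with_no_errors_is_all_T(self):
        config = SimulationConfig(
            seed=6,
            genes=(GenePlant("g1", "PCG", "+", "ctg1", 1000, (600,)),),
            ssrs=(), tandems=(), dispersed=(), mtpts=(),
            editing=(EditPlant("g1", 300, 1.0),),
            rna_error_rate=0.0,
        )
        genome, _, annotations, _ = simulate_mitogenome(config)
        reads, _ = simulate_rna_reads(annotations, genome, config)
        cds = annotations[0].spliced(genome.seq)
        left = cds[259:299]  # error-free context just before the site
        n_cov = 0
        for r in reads:
            i = r.seq.find(left)
            if i != -1 and i + 40 < len(r.seq):
                n_cov += 1
                assert r.seq[i + 40] == "T"
        assert n_cov >= 10

    def test_target_frequency_is_reached_binomially(self):
        """Observed T fraction concentrates around the planted frequency."""
        deviations_ok = 0
        n_rep = 10
        for seed in range(n_rep):
            config = SimulationConfig(
                seed=1000 + seed,
                genes=(GenePlant("g1", "PCG", "+", "ctg1", 1000, (600,)),),
                ssrs=(), tandems=(), dispersed=(), mtpts=(),
                editing=(EditPlant("g1", 300, 0.4),),
                rna_error_rate=0.0,
                rna_depth=100,
            )
            genome, _, annotations, _ = simulate_mitogenome(config)
            reads, _ = simulate_rna_reads(annotations, genome, config)
            cds = annotations[0].spliced(genome.seq)
            left = cds[299 - 20 : 299]
            n_cov = n_t = 0
            for r in reads:
                i = r.seq.find(left)
                if i == -1 or i + 21 > len(r.seq):
                    continue
                n_cov += 1
                n_t += r.seq[i + 20] == "T"
            assert n_cov >= 50
            se = np.sqrt(0.4 * 0.6 / n_cov)
            if abs(n_t / n_cov - 0.4) <= 3 * se:
                deviations_ok += 1
        assert deviations_ok >= n_rep - 1

    def test_editing_spec_on_unknown_gene_rejected(self):
        with pytest.raises(ConfigError):
            simulate_mitogenome(
                light_config(0, editing=(EditPlant("ghost", 10, 0.5),))
            )
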