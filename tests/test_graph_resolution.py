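import numpy as np
import pytest

from mitoresolve.graphres import (
    Conformation,
    UnresolvableGraphError,
    align_reads_to_segments,
    canonical_junction,
    count_junction_support,
    enumerate_recombinants,
    evidence_map,
    junction_label,
    predict_junction_amplicons,
    resolve_conformations,
)
from mitoresolve.io_core import AssemblyGraph, SequenceRecord, revcomp
from mitoresolve.synthetic import SimulationConfig, random_dna, simulate_hifi_reads, simulate_mitogenome
from .conftest import light_config


def _rng(seed):
    return np.random.default_rng(seed)


class TestAligner:
    def test_read_identical_to_segment(self):
        seg = random_dna(_rng(0), 2000, 0.45)
        alns = align_reads_to_segments(
            [SequenceRecord("r", seg)], {"s": seg}
        )
        (a,) = alns
        assert (a.read_start, a.read_end) == (0, 2000)
        assert (a.segment_start, a.segment_end) == (0, 2000)
        assert a.identity == 1.0
        assert a.segment_orient == "+"

    def test_junction_read_yields_two_adjacent_alignments(self):
        rng = _rng(1)
        ctg1 = random_dna(rng, 3000, 0.45)
        ctg3 = random_dna(rng, 2000, 0.45)
        read = ctg1[-800:] + ctg3[:900]
        alns = align_reads_to_segments(
            [SequenceRecord("r", read)], {"ctg1": ctg1, "ctg3": ctg3}
        )
        alns = sorted(alns, key=lambda a: a.read_start)
        assert [a.segment_id for a in alns] == ["ctg1", "ctg3"]
        assert alns[0].read_end == alns[1].read_start == 800
        assert alns[0].segment_end == 3000 and alns[1].segment_start == 0

    def test_empty_read_set(self):
        assert align_reads_to_segments([], {"s": "ACGT" * 100}) == []

    def test_reverse_strand_read_is_found(self):
        seg = random_dna(_rng(2), 1500, 0.45)
        (a,) = align_reads_to_segments(
            [SequenceRecord("r", revcomp(seg[200:1200]))], {"s": seg}
        )
        assert a.segment_orient == "-"
        assert (a.segment_start, a.segment_end) == (200, 1200)

    def test_too_short_segment_is_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            alns = align_reads_to_segments(
                [SequenceRecord("r", "ACGTACGTACGTACGTACGT")], {"tiny": "ACGTACG"}
            )
        assert alns == []


class TestJunctionSupport:
    def test_interior_reads_support_nothing(self):
        rng = _rng(3)
        segs = {"a": random_dna(rng, 3000, 0.45), "b": random_dna(rng, 3000, 0.45)}
        reads = [
            SequenceRecord("r1", segs["a"][500:1500]),
            SequenceRecord("r2", segs["b"][1000:2500]),
        ]
        alns = align_reads_to_segments(reads, segs)
        evidence = count_junction_support(alns, segs)
        assert all(ev.support == 0 for ev in evidence)

    def test_error_free_detection_equals_generator_truth(self):
        config = light_config(11, read_error_rate=0.0)
        genome, graph, _, truth = simulate_mitogenome(config)
        reads, expected = simulate_hifi_reads(genome, config, truth.junction_positions)
        alns = align_reads_to_segments(reads, graph.segments)
        evidence = count_junction_support(alns, graph.segments, graph=graph)
        detected = {junction_label(ev.junction): ev.support for ev in evidence}
        assert detected == expected

    def test_support_is_strand_invariant(self):
        config = light_config(12)
        genome, graph, _, truth = simulate_mitogenome(config)
        reads, _ = simulate_hifi_reads(genome, config, truth.junction_positions)
        flipped = [SequenceRecord(r.id, revcomp(r.seq)) for r in reads]
        ev1 = count_junction_support(
            align_reads_to_segments(reads, graph.segments), graph.segments, graph=graph
        )
        ev2 = count_junction_support(
            align_reads_to_segments(flipped, graph.segments), graph.segments, graph=graph
        )
        assert evidence_map(ev1) == evidence_map(ev2)

    def test_support_equals_read_id_count(self):
        config = light_config(13)
        genome, graph, _, truth = simulate_mitogenome(config)
        reads, _ = simulate_hifi_reads(genome, config, truth.junction_positions)
        alns = align_reads_to_segments(reads, graph.segments)
        for ev in count_junction_support(alns, graph.segments):
            assert ev.support == len(ev.read_ids)


def _toy_graph(lengths):
    g = AssemblyGraph(segments={k: "A" * v for k, v in lengths.items()})
    return g


class TestResolve:
    def test_repeat_topology_master_walk(self):
        g = _toy_graph({"ctg1": 240, "ctg2": 180, "ctg3": 40})
        for link in [("ctg1", "+", "ctg3", "+"), ("ctg3", "+", "ctg2", "+"),
                     ("ctg2", "+", "ctg3", "+"), ("ctg3", "+", "ctg1", "+")]:
            g.add_link(*link)
        support = {
            canonical_junction((a, oa), (b, ob)): 10
            for a, oa, b, ob in g.links
        }
        master = resolve_conformations(
            g, support, repeat_copy_numbers={"ctg1": 1, "ctg2": 1, "ctg3": 2}
        )
        expected = Conformation(
            (("ctg1", "+"), ("ctg3", "+"), ("ctg2", "+"), ("ctg3", "+")), 0, "master"
        )
        assert master.canonical() == expected.canonical()
        assert master.length == 240 + 180 + 2 * 40

    def test_single_self_looped_segment(self):
        g = _toy_graph({"one": 100})
        g.add_link("one", "+", "one", "+")
        support = {canonical_junction(("one", "+"), ("one", "+")): 4}
        master = resolve_conformations(g, support)
        assert master.walk == (("one", "+"),)
        assert master.length == 100

    def test_unsupported_junction_raises_structured_error(self):
        g = _toy_graph({"a": 300, "b": 200})
        g.add_link("a", "+", "b", "+")
        g.add_link("b", "+", "a", "+")
        support = {
            canonical_junction(("a", "+"), ("b", "+")): 5,
            canonical_junction(("b", "+"), ("a", "+")): 0,
        }
        with pytest.raises(UnresolvableGraphError) as err:
            resolve_conformations(g, support)
        assert err.value.unsupported

    def test_copy_numbers_inferred_from_depth_tags(self):
        g = _toy_graph({"u": 500, "r": 100, "v": 400})
        g.depth = {"u": 21.0, "r": 39.5, "v": 19.0}
        for link in [("u", "+", "r", "+"), ("r", "+", "v", "+"),
                     ("v", "+", "r", "+"), ("r", "+", "u", "+")]:
            g.add_link(*link)
        support = {
            canonical_junction((a, oa), (b, ob)): 3 for a, oa, b, ob in g.links
        }
        master = resolve_conformations(g, support)
        assert sum(1 for s, _ in master.walk if s == "r") == 2


class TestRecombinants:
    def test_no_repeats_gives_empty_list(self):
        master = Conformation((("a", "+"), ("b", "+")), 500, "master")
        assert enumerate_recombinants(master, [], {"a": 300, "b": 200}) == []

    def test_pair_lengths_sum_to_master(self, default_dataset):
        config, genome, graph, _, truth = default_dataset
        master = truth.true_master
        pairs = enumerate_recombinants(master, ["repeat"], graph.segment_lengths())
        assert len(pairs) == 1
        (c1, c2) = pairs[0]
        assert c1.length + c2.length == master.length
        assert {c.canonical() for c in (c1, c2)} == {
            c.canonical() for c in truth.true_subcircles
        }

    def test_three_occurrences_give_three_splits(self):
        walk = (("a", "+"), ("r", "+"), ("b", "+"), ("r", "+"), ("c", "+"), ("r", "+"))
        lengths = {"a": 100, "b": 150, "c": 200, "r": 50}
        master = Conformation(walk, sum(lengths[s] for s, _ in walk), "master")
        pairs = enumerate_recombinants(master, ["r"], lengths)
        assert len(pairs) == 3  # C(3, 2)
        for c1, c2 in pairs:
            assert c1.length + c2.length == master.length
            copies = sum(1 for c in (c1, c2) for s, _ in c.walk if s == "r")
            assert copies == 3  # conserved; the split puts >=1 in each circle
            assert all(any(s == "r" for s, _ in c.walk) for c in (c1, c2))

    def test_inverted_repeat_pair_is_skipped(self):
        walk = (("a", "+"), ("r", "+"), ("b", "+"), ("r", "-"))
        master = Conformation(walk, 400, "master")
        assert enumerate_recombinants(master, ["r"], {"a": 100, "b": 100, "r": 100}) == []


class TestAmplicons:
    def test_template_is_centered_on_the_join(self, default_dataset):
        config, genome, graph, _, truth = default_dataset
        amps = predict_junction_amplicons(truth.true_master, graph.segments, flank=1000)
        assert len(amps) == 4
        doubled = genome.seq + genome.seq
        L = len(genome.seq)
        for a in amps:
            assert len(a.template) == 2000
            assert a.template == doubled[(a.position - 1000) % L :][:2000]
            assert a.position in set(truth.junction_positions.values())

    def test_primer_product_length_is_additive(self, default_dataset):
        _, genome, graph, _, truth = default_dataset
        (amp,) = predict_junction_amplicons(
            truth.true_master, graph.segments, flank=1000
        )[:1]
        fwd = amp.template[600:620]  # 400 bp left of the join
        rev = revcomp(amp.template[1680:1700])  # ends 700 bp right of the join
        amps = predict_junction_amplicons(
            truth.true_master, graph.segments, flank=1000,
            primer_pairs=[(fwd, rev)] * 4,
        )
        assert amps[0].product_length == 1100
        assert amps[0].specific is True

    def test_missing_primer_flags_non_specific(self, default_dataset):
        _, _, graph, _, truth = default_dataset
        amps = predict_junction_amplicons(
            truth.true_master, graph.segments, flank=500,
            primer_pairs=[("GGGGGGGGGGGGGGGGGGGGGG", "CCCCCCCCCCCCCCCCCCCCCC")] * 4,
        )
        assert all(a.specific is False for a in amps)
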