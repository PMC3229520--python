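import numpy as np
import pytest

from phyloconflict.retro import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    Intron,
    PresencePattern,
    RetroLocus,
    anchor_orthologous_intron,
    call_presence_absence,
    harvest_introns,
    parse_repeat_annotations,
    read_gene_models_gff3,
    tally_support,
)
from phyloconflict.synthetic import (
    SpeciesTreeSpec,
    SyntheticConfig,
    build_species_tree,
    simulate_retro_loci,
    write_dataset,
)


def make_gene(rng, exon_lens, intron_lens):
    """Random gene sequence with alternating exons/introns; returns
    (sequence, exon coordinate list)."""
    seq, exons, pos = [], [], 0
    for i, el in enumerate(exon_lens):
        chunk = "".join(rng.choice(list("ACGT"), el))
        exons.append((pos, pos + el))
        seq.append(chunk)
        pos += el
        if i < len(intron_lens):
            il = intron_lens[i]
            seq.append("".join(rng.choice(list("ACGT"), il)))
            pos += il
    return "".join(seq), exons


class TestHarvestIntrons:
    def test_length_bounds_strict(self, rng):
        seq, exons = make_gene(rng, [200, 200, 200, 200], [300, 1000, 3000])
        introns, dropped = harvest_introns(exons, seq)
        assert [i.length for i in introns] == [1000]
        assert not dropped

    def test_included_with_flanks(self, rng):
        seq, exons = make_gene(rng, [100, 100], [1000])
        introns, _ = harvest_introns(exons, seq)
        (intron,) = introns
        assert len(intron.upstream_flank) == 80
        assert len(intron.downstream_flank) == 80
        assert intron.flanked_sequence in seq

    def test_single_exon_no_introns(self, rng):
        seq, exons = make_gene(rng, [500], [])
        introns, dropped = harvest_introns(exons, seq)
        assert introns == [] and dropped == []

    def test_short_exon_drops_locus(self, rng):
        seq, exons = make_gene(rng, [50, 200], [800])
        introns, dropped = harvest_introns(exons, seq)
        assert introns == []
        assert len(dropped) == 1 and "flank" in dropped[0]

    def test_minus_strand_normalized(self, rng):
        from Bio.Seq import Seq

        seq, exons = make_gene(rng, [100, 100], [500])
        plus, _ = harvest_introns(exons, seq, strand="+")
        n = len(seq)
        rc = str(Seq(seq).reverse_complement())
        minus_exons = [(n - e, n - s) for s, e in exons]
        minus, _ = harvest_introns(minus_exons, rc, strand="-")
        assert minus[0].sequence == plus[0].sequence
        assert minus[0].upstream_flank == plus[0].upstream_flank

    def test_out_of_order_exons(self, rng):
        with pytest.raises(ValueError, match="out of order"):
            harvest_introns([(0, 100), (50, 150)], "A" * 200)


class TestRepeatMaskerParsing:
    HEADER = (
        "   SW   perc perc perc  query  position in query  matching repeat\n"
        "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
        "\n"
    )

    def test_filter_to_line1(self, tmp_path):
        rows = [
            "1000 10.0 0.0 0.0 q1 101 400 (0) + L1MA1 LINE/L1 1 300 (0) 1",
            " 900 11.0 0.0 0.0 q1 500 600 (0) C MIR SINE/MIR 1 100 (0) 2",
            " 800 12.0 0.0 0.0 q2 11 310 (0) + L1MB2 LINE/L1 1 300 (0) 3",
            " 700 13.0 0.0 0.0 q2 400 450 (0) + AluY SINE/Alu 1 50 (0) 4",
            " 600 14.0 0.0 0.0 q3 21 320 (0) + L1ME LINE/L1 1 300 (0) 5",
        ]
        path = tmp_path / "rm.out"
        path.write_text(self.HEADER + "\n".join(rows) + "\n")
        annotations, skipped = parse_repeat_annotations(path)
        assert len(annotations) == 3
        assert skipped == 0
        first = annotations[0]
        assert (first.start, first.end) == (100, 400)  # 1-based -> half-open
        assert first.family == "LINE/L1"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.out"
        path.write_text("")
        annotations, skipped = parse_repeat_annotations(path)
        assert annotations == [] and skipped == 0

    def test_malformed_lines_counted(self, tmp_path):
        path = tmp_path / "bad.out"
        path.write_text("not a real line at all\n1000 10 0 0 q1 1 x (0) + L1 LINE/L1 1 2 (0) 1\n")
        annotations, skipped = parse_repeat_annotations(path)
        assert annotations == []
        assert skipped == 2

    def test_round_trip_through_synthetic_writer(self, tmp_path):
        spec = SpeciesTreeSpec(topology_id=14, internal_branch=5.0, outgroups=())
        cfg = SyntheticConfig(
            species_tree=spec, n_genes=1, gene_length=30, n_introns=8,
            insertion_rate=0.1, seed=31,
        )
        tree = build_species_tree(spec)
        loci = simulate_retro_loci(tree, cfg)
        write_dataset(cfg, tmp_path, loci=loci)
        annotations, skipped = parse_repeat_annotations(tmp_path / "introns" / "repeats.out")
        assert skipped == 0
        truth = [a for locus in loci for a in locus.annotations]
        assert len(annotations) == len(truth)
        for got, want in zip(annotations, truth):
            assert (got.start, got.end) == (want.start, want.end)
            assert got.family == "LINE/L1"


class TestAnchoring:
    @pytest.fixture
    def reference(self, rng):
        seq, exons = make_gene(rng, [150, 150], [700])
        introns, _ = harvest_introns(exons, seq, gene_id="ref")
        return introns[0], seq

    def test_mutated_target_recovered(self, rng, reference):
        intron, seq = reference
        # target = gene sequence with 5% substitutions
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < 0.05
        subs = rng.choice(list("ACGT"), hit.sum())
        arr[hit] = subs
        target = "".join(arr)
        span = anchor_orthologous_intron(intron, target)
        assert span is not None
        start, end = span
        assert abs(start - intron.start) <= 5
        assert abs(end - intron.end) <= 5

    def test_reverse_strand_recovered(self, reference):
        from Bio.Seq import Seq

        intron, seq = reference
        target = str(Seq(seq).reverse_complement())
        span = anchor_orthologous_intron(intron, target)
        assert span is not None
        n = len(seq)
        assert (n - span[1], n - span[0]) == (intron.start, intron.end)

    def test_absent_flank_not_found(self, rng, reference):
        intron, _ = reference
        target = "".join(rng.choice(list("ACGT"), 2000))
        assert anchor_orthologous_intron(intron, target) is None


class TestPresenceCalls:
    def locus(self, rows, interval):
        return RetroLocus("L", rows, insert_columns=[interval])

    def test_stem_insertion_informative(self):
        ins = "ACGT" * 25
        rows = {
            "a": "AAAA" + ins + "TTTT",
            "b": "AAAA" + ins + "TTTT",
            "c": "AAAA" + "-" * 100 + "TTTT",
            "d": "AAAA" + "-" * 100 + "TTTT",
        }
        pattern = call_presence_absence(self.locus(rows, (4, 104)))
        assert pattern.calls == {"a": PRESENT, "b": PRESENT, "c": ABSENT, "d": ABSENT}
        assert pattern.informative
        assert pattern.present_set == frozenset({"a", "b"})

    def test_present_in_all_uninformative(self):
        ins = "ACGT" * 25
        rows = {s: "AAAA" + ins + "TTTT" for s in "abcd"}
        pattern = call_presence_absence(self.locus(rows, (4, 104)))
        assert all(c == PRESENT for c in pattern.calls.values())
        assert not pattern.informative

    def test_n_run_ambiguous(self):
        ins = "ACGT" * 25
        rows = {
            "a": "AAAA" + ins + "TTTT",
            "b": "AAAA" + "N" * 100 + "TTTT",
            "c": "AAAA" + "-" * 100 + "TTTT",
            "d": "AAAA" + "-" * 100 + "TTTT",
        }
        pattern = call_presence_absence(self.locus(rows, (4, 104)))
        assert pattern.calls["b"] == AMBIGUOUS
        assert not pattern.informative

    def test_species_order_invariance(self):
        ins = "ACGT" * 25
        rows = {
            "a": "AAAA" + ins + "TTTT",
            "b": "AAAA" + ins + "TTTT",
            "c": "AAAA" + "-" * 100 + "TTTT",
            "d": "AAAA" + "-" * 100 + "TTTT",
        }
        p1 = call_presence_absence(self.locus(rows, (4, 104)))
        p2 = call_presence_absence(self.locus(dict(reversed(rows.items())), (4, 104)))
        assert p1.calls == p2.calls

    def test_interval_outside_alignment(self):
        rows = {"a": "ACGT", "b": "ACGT"}
        with pytest.raises(ValueError, match="interval"):
            call_presence_absence(RetroLocus("L", rows), interval=(0, 10))

    def test_simulated_truth_recovered_no_ils(self):
        spec = SpeciesTreeSpec(topology_id=14, internal_branch=30.0, outgroups=())
        cfg = SyntheticConfig(species_tree=spec, n_introns=40, insertion_rate=0.05,
                              seed=3)
        loci = simulate_retro_loci(build_species_tree(spec), cfg)
        checked = 0
        for locus in loci:
            for interval, carriers in zip(locus.insert_columns, locus.truth_carriers):
                if interval[1] - interval[0] < 60:
                    continue
                pattern = call_presence_absence(locus, interval)
                assert pattern.present_set == carriers
                checked += 1
        assert checked > 0


class TestTallySupport:
    def pattern(self, present, absent):
        calls = {s: PRESENT for s in present} | {s: ABSENT for s in absent}
        return PresencePattern("x", calls)

    def test_seven_markers_significant(self):
        patterns = [
            self.pattern({"Cow", "Dolphin"}, {"Pig", "Dog"}) for _ in range(7)
        ]
        tally = tally_support(patterns, {"Dolphin-Cow": {"Cow", "Dolphin"}})
        assert tally.counts["Dolphin-Cow"] == 7
        assert tally.significant["Dolphin-Cow"]

    def test_two_markers_not_significant(self):
        patterns = [self.pattern({"A", "B"}, {"C", "D"}) for _ in range(2)]
        tally = tally_support(patterns, {"AB": {"A", "B"}})
        assert tally.counts["AB"] == 2
        assert not tally.significant["AB"]

    def test_empty_patterns(self):
        tally = tally_support([], {"AB": {"A", "B"}})
        assert tally.counts == {"AB": 0}

    def test_uninformative_not_counted(self):
        patterns = [self.pattern({"A"}, {"B", "C", "D"})]  # single present
        tally = tally_support(patterns, {"A-only": {"A"}})
        assert tally.counts["A-only"] == 0

    def test_unknown_taxa_rejected(self):
        patterns = [self.pattern({"A", "B"}, {"C", "Z"})]
        with pytest.raises(KeyError):
            tally_support(patterns, {"AB": {"A", "B"}}, taxa={"A", "B", "C", "D"})


class TestGff3Intake:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t2000\t.\t+\t.\tID=gene1\n"
        "chr1\tsrc\texon\t1\t150\t.\t+\t.\tID=e1;Parent=tx1\n"
        "chr1\tsrc\texon\t951\t1100\t.\t+\t.\tID=e2;Parent=tx1\n"
        "chr2\tsrc\texon\t11\t110\t.\t-\t.\tID=e3;Parent=tx2\n"
    )

    def test_exons_grouped_and_converted(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(self.GFF)
        models = read_gene_models_gff3(path)
        assert set(models) == {"tx1", "tx2"}
        assert models["tx1"]["exons"] == [(0, 150), (950, 1100)]
        assert models["tx2"]["strand"] == "-"

    def test_feeds_harvest(self, tmp_path, rng):
        path = tmp_path / "genes.gff3"
        path.write_text(self.GFF)
        models = read_gene_models_gff3(path)
        seq = "".join(rng.choice(list("ACGT"), 1100))
        introns, _ = harvest_introns(
            models["tx1"]["exons"], seq, gene_id="tx1"
        )
        assert len(introns) == 1 and introns[0].length == 800
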