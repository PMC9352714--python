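"""Read filtering, anchored guide/UMI matching and directional clone merging."""

import numpy as np
import networkx as nx
import pytest

import umifit as u
from umifit.clone_extraction import (
    FORWARD_ANCHOR,
    REVERSE_ANCHOR,
    CloneRecord,
    CloneTable,
    ReadPair,
)
from umifit.library_design import GuideRecord, LibraryDesign, reverse_complement


def _pair(q_fwd, q_rev, n=30):
    return ReadPair("A" * n, [q_fwd] * n, "C" * n, [q_rev] * n)


class TestQualityFilter:
    def test_both_mates_must_pass(self):
        pairs = [_pair(35, 31), _pair(35, 29), _pair(29, 35), _pair(30, 30)]
        kept = list(u.quality_filter(pairs))
        assert len(kept) == 2

    def test_fractional_mean_below_threshold_removed(self):
        # mean 29.5 on the reverse mate
        p = ReadPair("AA", [35, 35], "CC", [30, 29])
        assert list(u.quality_filter([p])) == []

    def test_empty_stream(self):
        assert list(u.quality_filter([])) == []

    def test_length_mismatch_dropped(self):
        p = ReadPair("AAA", [35, 35], "CC", [35, 35])
        assert list(u.quality_filter([p])) == []


@pytest.fixture(scope="module")
def tiny_lib():
    return u.make_random_library(9, 3, seed=17)


def _fwd_read(guide_seq, pad="ACGTACGTAC", spacer="G" * 23, tail="TTTT"):
    return pad + FORWARD_ANCHOR + spacer + guide_seq + tail


class TestExtractGuide:
    def test_window_rule_exact_match(self, tiny_lib):
        g = tiny_lib.guides[4]
        assert u.extract_guide(_fwd_read(g.sequence), tiny_lib) == g.guide_id

    def test_one_mismatch_assigned(self, tiny_lib):
        g = tiny_lib.guides[2]
        mutated = ("G" if g.sequence[7] != "G" else "T") + ""
        seq = g.sequence[:7] + mutated + g.sequence[8:]
        assert u.extract_guide(_fwd_read(seq), tiny_lib) == g.guide_id

    def test_equidistant_tie_discarded(self):
        # two guides at Hamming distance 2; the midpoint window is 1 from each
        a = "A" * 20
        b = "C" + "A" * 18 + "C"
        mid = "C" + "A" * 19  # d(mid,a)=1, d(mid,b)=1
        lib = LibraryDesign("two", [GuideRecord("ga", a), GuideRecord("gb", b)])
        assert u.extract_guide(_fwd_read(mid), lib) is None

    def test_no_anchor_returns_none(self, tiny_lib):
        assert u.extract_guide("A" * 80, tiny_lib) is None

    def test_window_out_of_bounds(self, tiny_lib):
        g = tiny_lib.guides[0]
        truncated = ("ACGT" + FORWARD_ANCHOR + "G" * 23 + g.sequence)[:-10]
        assert u.extract_guide(truncated, tiny_lib) is None

    def test_never_assigns_beyond_max_mismatch(self, tiny_lib):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seqs = {g.guide_id: g.sequence for g in tiny_lib.guides}
        for _ in range(200):
            window = "".join(rng.choice(bases, 20))
            hit = u.extract_guide(_fwd_read(window), tiny_lib)
            if hit is not None:
                d = sum(x != y for x, y in zip(window, seqs[hit]))
                assert d <= 1


def _rev_read(umi_fwd, pad="TTGCAG", spacer="CGAAT", tail="GG"):
    return pad + REVERSE_ANCHOR + spacer + reverse_complement(umi_fwd) + tail


class TestExtractUmi:
    template = u.UmiTemplate()

    def _umi(self, seed=0):
        return self.template.realize(np.random.default_rng(seed))

    def test_exact_window_reverse_complemented(self):
        umi = self._umi(1)
        assert u.extract_umi(_rev_read(umi), self.template) == umi

    def test_one_fixed_position_mismatch_accepted(self):
        umi = self._umi(2)
        rc = reverse_complement(umi)
        # reverse pattern NNGTT...: index 2 is a fixed G; corrupt it
        corrupted = rc[:2] + ("A" if rc[2] != "A" else "C") + rc[3:]
        read = "TTGCAG" + REVERSE_ANCHOR + "CGAAT" + corrupted + "GG"
        out = u.extract_umi(read, self.template)
        assert out == reverse_complement(corrupted)

    def test_two_mismatches_rejected(self):
        umi = self._umi(3)
        rc = reverse_complement(umi)
        corrupted = list(rc)
        # positions 2 and 3 are fixed G, T in the reverse pattern
        corrupted[2] = "A" if rc[2] != "A" else "C"
        corrupted[3] = "A" if rc[3] != "A" else "C"
        corrupted = "".join(corrupted)
        read = "TTGCAG" + REVERSE_ANCHOR + corrupted + "G" * 23
        # brute-force: no 27-nt window within 1 mismatch of the pattern
        rc_pat = self.template.reverse_complemented()
        region = read[read.find(REVERSE_ANCHOR) + len(REVERSE_ANCHOR) :][:50]
        assert not any(
            rc_pat.matches(region[i : i + 27], max_mismatch=1)
            for i in range(len(region) - 26)
        )
        assert u.extract_umi(read, self.template) is None

    def test_leftmost_window_wins(self):
        umi1, umi2 = self._umi(4), self._umi(5)
        read = "AA" + REVERSE_ANCHOR + reverse_complement(umi1) + reverse_complement(umi2)
        assert u.extract_umi(read, self.template) == umi1

    def test_no_anchor(self):
        assert u.extract_umi("ACGT" * 30, self.template) is None


class TestStandardizeDepth:
    def test_under_cap_identity(self):
        recs = [("g", f"u{i}") for i in range(1500)]
        assert u.standardize_depth(recs, cap=2_000_000, seed=0) == recs

    def test_cap_exact(self):
        out = u.standardize_depth(np.arange(5000), cap=1000, seed=1)
        assert len(out) == 1000
        assert len(set(out)) == 1000  # without replacement

    def test_deterministic(self):
        recs = list(range(3000))
        a = u.standardize_depth(recs, cap=500, seed=42)
        b = u.standardize_depth(recs, cap=500, seed=42)
        assert a == b


def _table(counts: dict[str, int], guide="g1"):
    return CloneTable(
        sample_id="s", records=[CloneRecord(guide, umi, c) for umi, c in counts.items()]
    )


def _umi_at_distance(base, positions):
    chars = list(base)
    for p in positions:
        chars[p] = "A" if chars[p] != "A" else "C"
    return "".join(chars)


BASE_UMI = u.UmiTemplate().realize(np.random.default_rng(99))


class TestDirectionalMerge:
    def test_merge_when_inequality_holds(self):
        a, b = BASE_UMI, _umi_at_distance(BASE_UMI, [3])
        out = u.directional_merge(_table({a: 10, b: 4}))
        assert len(out) == 1
        assert out.records[0].count == 14
        assert out.records[0].umi == a  # 10 > 2*4-1

    def test_no_merge_when_inequality_fails(self):
        a, b = BASE_UMI, _umi_at_distance(BASE_UMI, [3])
        out = u.directional_merge(_table({a: 7, b: 4}))
        assert len(out) == 2  # 7 > 7 is false

    def test_single_clone_unchanged(self):
        out = u.directional_merge(_table({BASE_UMI: 5}))
        assert len(out) == 1 and out.records[0].count == 5

    def test_chain_merges_into_one_component(self):
        a = BASE_UMI
        b = _umi_at_distance(a, [2])
        c = _umi_at_distance(a, [2, 9])  # d(a,b)=d(b,c)=1, d(a,c)=2
        out = u.directional_merge(_table({a: 100, b: 40, c: 15}))
        assert len(out) == 1
        assert out.records[0].count == 155
        assert out.records[0].umi == a

    def test_total_reads_conserved_and_idempotent_on_examples(self):
        a = BASE_UMI
        b = _umi_at_distance(a, [2])
        c = _umi_at_distance(a, [2, 9])
        t = _table({a: 100, b: 40, c: 15})
        merged = u.directional_merge(t)
        assert merged.total_reads == t.total_reads
        again = u.directional_merge(merged)
        assert again.to_frame().sort_values("umi").equals(
            merged.to_frame().sort_values("umi")
        )

    def _oracle(self, counts):
        umis = list(counts)
        g = nx.Graph()
        g.add_nodes_from(umis)
        for i, a in enumerate(umis):
            for b in umis[i + 1 :]:
                d = sum(x != y for x, y in zip(a, b))
                na, nb = max(counts[a], counts[b]), min(counts[a], counts[b])
                if d == 1 and na > 2 * nb - 1:
                    g.add_edge(a, b)
        out = {}
        for comp in nx.connected_components(g):
            rep = min(comp, key=lambda x: (-counts[x], x))
            out[rep] = sum(counts[x] for x in comp)
        return out

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for rep in range(25):
            n = int(rng.integers(2, 50))
            # cluster UMIs around a few centers so Hamming-1 pairs are common
            centers = [u.UmiTemplate().realize(rng) for _ in range(max(1, n // 6))]
            counts = {}
            while len(counts) < n:
                c = centers[rng.integers(len(centers))]
                umi = _umi_at_distance(c, rng.choice(27, rng.integers(0, 3), replace=False))
                counts.setdefault(umi, int(rng.integers(1, 200)))
            merged = u.directional_merge(_table(counts))
            got = {r.umi: r.count for r in merged.records}
            assert got == self._oracle(counts)


class TestExtractClones:
    def test_zero_error_round_trip(self, tmp_path):
        lib = u.make_fixture("notch")
        cfg = u.SimulationConfig(
            library=lib, seed=4, clones_per_guide=4, umi_error_rate=0.0,
            family="nb", family_params=dict(mu=5.0, r=1.0),
        )
        sim = u.simulate_screen(cfg, make_fastq=True, fastq_prefix=tmp_path / "rt")
        table = u.extract_clones(sim.fastq_fwd, sim.fastq_rev, lib, seed=1)
        a = sim.clone_table.to_frame().sort_values(["guide_id", "umi"]).reset_index(drop=True)
        b = table.to_frame().sort_values(["guide_id", "umi"]).reset_index(drop=True)
        assert a[["guide_id", "umi", "reads"]].equals(b[["guide_id", "umi", "reads"]])

    def test_umi_errors_absorbed_by_merging(self, tmp_path):
        lib = u.make_fixture("notch")
        cfg = u.SimulationConfig(
            library=lib, seed=5, clones_per_guide=5, umi_error_rate=0.003,
            family="nb", family_params=dict(mu=30.0, r=1.0),
        )
        sim = u.simulate_screen(cfg, make_fastq=True, fastq_prefix=tmp_path / "err")
        table = u.extract_clones(sim.fastq_fwd, sim.fastq_rev, lib, seed=1)
        n_true = len(sim.clone_table)
        assert table.stage_counts["clones_raw"] > 1.5 * n_true  # errors inflate raw clones
        assert abs(len(table) - n_true) / n_true < 0.06  # merging restores them

    def test_no_anchors_gives_empty_table(self, tmp_path):
        lib = u.make_fixture("notch")
        f1 = tmp_path / "a.R1.fastq"
        f2 = tmp_path / "a.R2.fastq"
        f1.write_text("@r1\nACGTACGTACGTACGT\n+\nFFFFFFFFFFFFFFFF\n")
        f2.write_text("@r1\nTGCATGCATGCATGCA\n+\nFFFFFFFFFFFFFFFF\n")
        table = u.extract_clones(f1, f2, lib, seed=0)
        assert len(table) == 0 and table.total_reads == 0


class TestCloneTableIO:
    def test_round_trip(self, tmp_path):
        t = _table({BASE_UMI: 5, _umi_at_distance(BASE_UMI, [1, 5]): 2})
        path = tmp_path / "clones.tsv"
        u.write_clone_table(t, path)
        back = u.read_clone_table(path)
        assert back.to_frame().equals(t.to_frame())

    def test_malformed_row_reported(self, tmp_path):
        path = tmp_path / "clones.tsv"
        path.write_text(
            "sample_id\tguide_id\tumi\treads\n"
            f"s\tg1\t{BASE_UMI}\t5\n"
            f"s\tg1\t{'A' * 10}\t2\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            u.read_clone_table(path)
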