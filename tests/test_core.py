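import random

import pytest
from hypothesis import given, strategies as st

from contigscreen.core import (
    UNCLASSIFIED,
    ProteinTaxonCall,
    QueryGenomeSpec,
    alien_score_per_protein,
    call_protein_taxon,
    contig_consensus,
    decontaminate,
    trim_hit_list,
)
from contigscreen.hits import HitList

BACTERIA, YEAST, BASIDIO, HUMAN, NOCLASS = 562, 4932, 5346, 9606, 7777


@pytest.fixture(scope="module")
def fungus_genome(taxonomy):
    return QueryGenomeSpec("fungus1", taxonomy[4932])


def hits_by_kingdom(make_hit_list, taxids):
    """Hit list with strictly decreasing bitscores over the given taxids."""
    return make_hit_list(
        "q", [(t, 1000 - i, 90.0) for i, t in enumerate(taxids)]
    )


class TestTrimHitList:
    def test_prefix_stops_at_first_label_change(self, taxonomy, make_hit_list):
        # kingdom labels: Fungi Fungi Fungi Bacteria_k Fungi -> prefix 3
        hl = hits_by_kingdom(make_hit_list, [YEAST, BASIDIO, YEAST, BACTERIA, YEAST])
        trimmed = trim_hit_list(hl, "kingdom", taxonomy)
        assert len(trimmed) == 3
        assert all(h.subject_taxid in (YEAST, BASIDIO) for h in trimmed)

    def test_single_hit_keeps_prefix_of_one(self, taxonomy, make_hit_list):
        hl = hits_by_kingdom(make_hit_list, [YEAST])
        assert len(trim_hit_list(hl, "kingdom", taxonomy)) == 1

    def test_empty_list_trims_to_empty(self, taxonomy):
        assert len(trim_hit_list(HitList("q", ()), "kingdom", taxonomy)) == 0

    def test_absent_rank_terminates_prefix(self, taxonomy, make_hit_list):
        hl = hits_by_kingdom(make_hit_list, [BASIDIO, NOCLASS, BASIDIO])
        assert len(trim_hit_list(hl, "class", taxonomy)) == 1

    def test_absent_best_hit_trims_to_empty(self, taxonomy, make_hit_list):
        hl = hits_by_kingdom(make_hit_list, [NOCLASS, BASIDIO])
        assert len(trim_hit_list(hl, "class", taxonomy)) == 0

    def test_matches_prefix_scan_oracle_on_random_sequences(
        self, taxonomy, make_hit_list
    ):
        rng = random.Random(11)
        pool = [BACTERIA, YEAST, BASIDIO, HUMAN]
        for _ in range(200):
            taxids = [rng.choice(pool) for _ in range(rng.randint(1, 12))]
            hl = hits_by_kingdom(make_hit_list, taxids)
            labels = [taxonomy.label_at_rank(t, "kingdom") for t in taxids]
            expected = 0
            for lab in labels:  # independent prefix scan
                if lab != labels[0]:
                    break
                expected += 1
            assert len(trim_hit_list(hl, "kingdom", taxonomy)) == expected


class TestCallProteinTaxon:
    def test_no_hits_is_unclassified_with_zero_confidence(self, taxonomy):
        call = call_protein_taxon(HitList("q", ()), "kingdom", taxonomy)
        assert call.label == UNCLASSIFIED
        assert call.confidence == 0.0
        assert call.n_hits_total == 0

    def test_unanimous_hits_give_full_confidence(self, taxonomy, make_hit_list):
        hl = hits_by_kingdom(make_hit_list, [YEAST] * 20)
        call = call_protein_taxon(hl, "kingdom", taxonomy, cap=10)
        assert (call.label, call.confidence) == ("Fungi", 1.0)
        assert call.n_hits_total == 20
        assert call.n_hits_retained == 20

    def test_confidence_counts_agreement_in_top_cap_window(
        self, taxonomy, make_hit_list
    ):
        # top-10 kingdom labels: B B B F F F F F F F -> call B at 3/10
        hl = hits_by_kingdom(make_hit_list, [BACTERIA] * 3 + [YEAST] * 7)
        call = call_protein_taxon(hl, "kingdom", taxonomy, cap=10)
        assert call.label == "Bacteria_k"
        assert call.confidence == pytest.approx(0.3)
        assert call.n_hits_retained == 3

    def test_short_lists_use_available_count_as_denominator(
        self, taxonomy, make_hit_list
    ):
        hl = hits_by_kingdom(make_hit_list, [YEAST, BACTERIA])
        call = call_protein_taxon(hl, "kingdom", taxonomy, cap=10)
        assert call.confidence == pytest.approx(0.5)

    def test_absent_rank_on_best_hit_is_unclassified(self, taxonomy, make_hit_list):
        hl = hits_by_kingdom(make_hit_list, [NOCLASS, BASIDIO])
        call = call_protein_taxon(hl, "class", taxonomy)
        assert call.label == UNCLASSIFIED

    def test_call_invariant_enforced(self):
        with pytest.raises(ValueError):
            ProteinTaxonCall("p", "kingdom", UNCLASSIFIED, 0.5, 1, 1)


def make_calls(labels, prefix="p"):
    return [
        ProteinTaxonCall(
            f"{prefix}{i}", "kingdom", lab,
            0.0 if lab == UNCLASSIFIED else 1.0,
            0 if lab == UNCLASSIFIED else 1,
            0 if lab == UNCLASSIFIED else 1,
        )
        for i, lab in enumerate(labels)
    ]


class TestContigConsensus:
    def run_one_contig(self, labels, genome, threshold=0.5):
        calls = make_calls(labels)
        membership = {c.protein_id: "ctg1" for c in calls}
        (verdict,) = contig_consensus(calls, membership, genome, "kingdom",
                                      threshold=threshold)
        return verdict

    def test_all_alien_contig_removed(self, fungus_genome):
        v = self.run_one_contig(["Bacteria_k"] * 5, fungus_genome)
        assert v.decision == "REMOVE"
        assert v.alien_fraction == 1.0

    def test_single_alien_among_ten_host_votes_kept(self, fungus_genome):
        v = self.run_one_contig(["Bacteria_k"] + ["Fungi"] * 10, fungus_genome)
        assert v.decision == "KEEP"
        assert v.alien_fraction == pytest.approx(1 / 11)

    def test_fully_unclassified_contig_retained(self, fungus_genome):
        v = self.run_one_contig([UNCLASSIFIED] * 4, fungus_genome)
        assert v.decision == "KEEP"
        assert v.alien_fraction == 0.0

    def test_unclassified_votes_excluded_from_denominator(self, fungus_genome):
        v = self.run_one_contig(
            ["Bacteria_k", "Fungi", UNCLASSIFIED, UNCLASSIFIED], fungus_genome
        )
        assert v.alien_fraction == pytest.approx(0.5)
        assert v.decision == "REMOVE"

    def test_dominant_alien_label_ties_break_lexicographically(self, fungus_genome):
        v = self.run_one_contig(["Metazoa", "Bacteria_k"], fungus_genome)
        assert v.dominant_alien_label == "Bacteria_k"

    def test_missing_membership_lists_offenders(self, fungus_genome):
        calls = make_calls(["Fungi", "Fungi"])
        with pytest.raises(KeyError, match="p1"):
            contig_consensus(calls, {"p0": "ctg1"}, fungus_genome, "kingdom")

    def test_matches_brute_force_recount(self, fungus_genome):
        # independent recount over randomly scattered contigs
        rng = random.Random(5)
        labels = ["Fungi", "Bacteria_k", "Metazoa", UNCLASSIFIED]
        calls = make_calls([rng.choice(labels) for _ in range(120)])
        membership = {c.protein_id: f"ctg{rng.randint(0, 19)}" for c in calls}
        verdicts = {
            v.contig_id: v
            for v in contig_consensus(calls, membership, fungus_genome,
                                      "kingdom", threshold=0.5)
        }
        by_contig = {}
        for c in calls:
            by_contig.setdefault(membership[c.protein_id], []).append(c.label)
        assert set(verdicts) == set(by_contig)
        for contig, labs in by_contig.items():
            host = sum(1 for l in labs if l == "Fungi")
            alien = sum(1 for l in labs if l not in ("Fungi", UNCLASSIFIED))
            v = verdicts[contig]
            assert (v.votes_host, v.votes_alien) == (host, alien)
            assert v.votes_unclassified == labs.count(UNCLASSIFIED)
            expected = "REMOVE" if (host + alien) and alien / (host + alien) >= 0.5 else "KEEP"
            assert v.decision == expected

    @given(
        contigs=st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6)),
            min_size=1, max_size=8,
        ).filter(lambda cfg: all(sum(t) > 0 for t in cfg)),
        threshold=st.floats(0.05, 1.0),
        bump=st.floats(0.0, 0.95),
    )
    def test_raising_threshold_never_removes_more(
        self, fungus_genome, contigs, threshold, bump
    ):
        labels, membership = [], {}
        for ci, (h, a, u) in enumerate(contigs):
            for lab in ["Fungi"] * h + ["Bacteria_k"] * a + [UNCLASSIFIED] * u:
                pid = f"c{ci}_p{len(labels)}"
                labels.append(lab)
                membership[pid] = f"ctg{ci}"
        calls = [
            ProteinTaxonCall(pid, "kingdom", lab,
                             0.0 if lab == UNCLASSIFIED else 1.0,
                             0 if lab == UNCLASSIFIED else 1,
                             0 if lab == UNCLASSIFIED else 1)
            for pid, lab in zip(membership, labels)
        ]
        higher = min(1.0, threshold + bump)
        removed_low = sum(
            v.decision == "REMOVE"
            for v in contig_consensus(calls, membership, fungus_genome,
                                      "kingdom", threshold)
        )
        removed_high = sum(
            v.decision == "REMOVE"
            for v in contig_consensus(calls, membership, fungus_genome,
                                      "kingdom", higher)
        )
        assert removed_high <= removed_low


def tiny_run(taxonomy, make_hit_list, tmp_path=None, threshold=0.5):
    """Yeast genome: 2 host contigs + 1 bacterial contig + 1 no-hit contig."""
    proteome = {f"h{i}": "MKT" * 20 for i in range(4)}
    proteome.update({f"b{i}": "WLV" * 20 for i in range(2)})
    proteome.update({f"u{i}": "GGG" * 20 for i in range(2)})
    membership = {
        "h0": "ctgA", "h1": "ctgA", "h2": "ctgB", "h3": "ctgB",
        "b0": "ctgC", "b1": "ctgC", "u0": "ctgD", "u1": "ctgD",
    }
    hit_lists = {
        **{f"h{i}": make_hit_list(f"h{i}", [(4932, 100, 90), (5346, 90, 80)])
           for i in range(4)},
        **{f"b{i}": make_hit_list(f"b{i}", [(562, 100, 90)]) for i in range(2)},
    }
    genome = QueryGenomeSpec("yeast", taxonomy[4932])
    return decontaminate(
        proteome, membership, hit_lists, taxonomy, genome,
        rank="kingdom", threshold=threshold, min_pident=20.0,
        out_dir=tmp_path,
    )


class TestDecontaminate:
    def test_alien_contig_removed_others_kept(self, taxonomy, make_hit_list, tmp_path):
        report = tiny_run(taxonomy, make_hit_list, tmp_path / "out")
        assert report.removed_set == {"b0", "b1"}
        assert report.kept_set == {"h0", "h1", "h2", "h3", "u0", "u1"}
        cleaned = (tmp_path / "out" / "cleaned.faa").read_text()
        assert ">b0" not in cleaned and ">h0" in cleaned
        for name in ("cleaned.faa", "removed.tsv", "verdicts.tsv", "summary.json"):
            assert (tmp_path / "out" / name).exists()

    def test_no_alien_contigs_keeps_everything(self, taxonomy, make_hit_list):
        proteome = {"h0": "MKT" * 10, "h1": "MKT" * 10}
        membership = {"h0": "c1", "h1": "c1"}
        hit_lists = {p: make_hit_list(p, [(4932, 100, 90)]) for p in proteome}
        report = decontaminate(proteome, membership, hit_lists, taxonomy,
                               QueryGenomeSpec("y", taxonomy[4932]), rank="kingdom")
        assert report.removed_set == frozenset()
        assert report.kept_set == {"h0", "h1"}

    def test_id_mismatch_fails_before_classification(self, taxonomy):
        with pytest.raises(KeyError, match="orphan"):
            decontaminate({"orphan": "MKT"}, {}, {}, taxonomy,
                          QueryGenomeSpec("y", taxonomy[4932]))

    def test_partition_and_contig_atomicity(self, taxonomy, make_hit_list):
        report = tiny_run(taxonomy, make_hit_list)
        all_ids = set(report.kept_proteins) | set(report.removed_proteins)
        assert all_ids == set(report.membership)
        assert not report.kept_set & report.removed_set
        for contig in set(report.membership.values()):
            members = [p for p, c in report.membership.items() if c == contig]
            states = {p in report.removed_set for p in members}
            assert len(states) == 1  # all kept or all removed together

    def test_min_pident_filter_changes_calls(self, taxonomy, make_hit_list):
        # the only hit sits below the 20% identity floor -> unclassified
        proteome = {"p0": "MKT" * 10}
        membership = {"p0": "c1"}
        hit_lists = {"p0": make_hit_list("p0", [(562, 100, 15.0)])}
        genome = QueryGenomeSpec("y", taxonomy[4932])
        report = decontaminate(proteome, membership, hit_lists, taxonomy,
                               genome, rank="kingdom", min_pident=20.0)
        assert report.calls["p0"].label == UNCLASSIFIED
        assert report.kept_set == {"p0"}
        report2 = decontaminate(proteome, membership, hit_lists, taxonomy,
                                genome, rank="kingdom", min_pident=10.0)
        assert report2.calls["p0"].label == "Bacteria_k"
        assert report2.removed_set == {"p0"}

    def test_reruns_are_byte_identical(self, taxonomy, make_hit_list, tmp_path):
        tiny_run(taxonomy, make_hit_list, tmp_path / "a")
        tiny_run(taxonomy, make_hit_list, tmp_path / "b")
        for name in ("cleaned.faa", "removed.tsv", "verdicts.tsv", "summary.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()


class TestAlienScore:
    def test_scores_equal_contig_alien_fraction(self, taxonomy, make_hit_list):
        report = tiny_run(taxonomy, make_hit_list)
        scores = alien_score_per_protein(report)
        assert scores["h0"] == 0.0
        assert scores["b0"] == 1.0
        assert scores["u0"] == 0.0

    def test_mixed_contig_score_is_fractional(self, fungus_genome, taxonomy):
        calls = make_calls(["Bacteria_k"] + ["Fungi"] * 10)
        membership = {c.protein_id: "ctg1" for c in calls}
        verdicts = contig_consensus(calls, membership, fungus_genome, "kingdom")
        assert verdicts[0].alien_fraction == pytest.approx(1 / 11)
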