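import numpy as np
import pytest

from strandex.classify import (
    CategoryLabel,
    Thresholds,
    classify_transcripts,
    find_putative_orfs,
    propagate_sense_to_isoforms,
    summarize_categories,
)
from strandex.io import AlignmentHit, TranscriptRecord

STOPS = {"TAA", "TAG", "TGA"}


def tx(tid, n=300, seq=None):
    return TranscriptRecord(tid, seq if seq is not None else "C" * n)


def hit(q, s, db, orient, qcov=0.5, scov=0.5, ident=90.0, ev=1e-30, bs=100.0):
    return AlignmentHit(q, s, db, orient, qcov, scov, ident, ev, bs)


def labels_of(transcripts, hits, **kw):
    return {
        l.transcript_id: l
        for l in classify_transcripts(transcripts, hits, Thresholds(**kw))
    }


class TestSequentialRules:
    def test_sense_above_60pct_protein_coverage(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of([t], [hit(t.transcript_id, "NP_1", "proteome", "sense", scov=0.61)])
        assert lab[t.transcript_id].category == "sense"
        assert lab[t.transcript_id].evidence == ("NP_1",)

    def test_exactly_60pct_is_not_sense(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of([t], [hit(t.transcript_id, "NP_1", "proteome", "sense", scov=0.60)])
        assert lab[t.transcript_id].category == "unknown"

    def test_nr_fallback_rescues_sense(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of(
            [t],
            [
                hit(t.transcript_id, "NP_1", "proteome", "sense", scov=0.40),
                hit(t.transcript_id, "gi|1", "nr_protein", "sense", scov=0.70),
            ],
        )
        assert lab[t.transcript_id].category == "sense"

    def test_antisense_to_both(self):
        sense = tx("comp1_c0_seq1")
        anti = tx("comp2_c0_seq1")
        hits = [
            hit(sense.transcript_id, "NP_1", "proteome", "sense", scov=0.9),
            hit(anti.transcript_id, "NP_2", "proteome", "antisense", scov=0.51),
            hit(anti.transcript_id, sense.transcript_id, "sense_transcript",
                "antisense", qcov=0.85, ident=96.0),
        ]
        lab = labels_of([sense, anti], hits)
        assert lab[anti.transcript_id].category == "antisense_to_both"

    def test_antisense_to_protein_only(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of([t], [hit(t.transcript_id, "NP_1", "proteome", "antisense", scov=0.51)])
        assert lab[t.transcript_id].category == "antisense_to_protein"
        # exactly 50% falls through
        lab = labels_of([t], [hit(t.transcript_id, "NP_1", "proteome", "antisense", scov=0.50)])
        assert lab[t.transcript_id].category == "unknown"

    def test_antisense_to_sense_requires_partner_proteome_hit(self):
        sense = tx("comp1_c0_seq1")
        anti = tx("comp2_c0_seq1")
        base = [
            hit(anti.transcript_id, sense.transcript_id, "sense_transcript",
                "antisense", qcov=0.85, ident=96.0),
        ]
        # partner rescued to sense via nr only (no proteome hit): hit ignored
        nr_only = base + [
            hit(sense.transcript_id, "gi|1", "nr_protein", "sense", scov=0.9)
        ]
        lab = labels_of([sense, anti], nr_only)
        assert lab[anti.transcript_id].category == "unknown"
        # partner with a proteome hit qualifies
        with_prot = base + [
            hit(sense.transcript_id, "NP_1", "proteome", "sense", scov=0.9)
        ]
        lab = labels_of([sense, anti], with_prot)
        assert lab[anti.transcript_id].category == "antisense_to_sense"
        assert lab[anti.transcript_id].evidence == (sense.transcript_id,)

    def test_lncrna_boundaries(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of([t], [hit(t.transcript_id, "chr1", "genome", "sense",
                                  qcov=0.81, ident=95.0)])
        assert lab[t.transcript_id].category == "lncRNA"
        # identity below the inclusive 95 bound
        lab = labels_of([t], [hit(t.transcript_id, "chr1", "genome", "sense",
                                  qcov=0.81, ident=94.99)])
        assert lab[t.transcript_id].category == "unknown"
        # coverage exactly at the strict 0.80 bound
        lab = labels_of([t], [hit(t.transcript_id, "nt1", "nt", "sense",
                                  qcov=0.80, ident=99.0)])
        assert lab[t.transcript_id].category == "unknown"

    def test_no_hits_is_unknown(self):
        t = tx("comp1_c0_seq1")
        lab = labels_of([t], [])
        assert lab[t.transcript_id].category == "unknown"

    def test_unknown_transcript_reference_rejected(self):
        t = tx("comp1_c0_seq1")
        with pytest.raises(ValueError, match="comp9_c9_seq9"):
            classify_transcripts(
                [t], [hit("comp9_c9_seq9", "NP_1", "proteome", "sense", scov=0.9)]
            )

    def test_nr_feeds_antisense_flag(self):
        t = tx("comp1_c0_seq1")
        hits = [hit(t.transcript_id, "gi|1", "nr_protein", "antisense", scov=0.7)]
        assert labels_of([t], hits)[t.transcript_id].category == "antisense_to_protein"
        lab = labels_of([t], hits, nr_feeds_antisense=False)
        assert lab[t.transcript_id].category == "unknown"


class TestIsoformPropagation:
    def test_variant_becomes_sense(self):
        t1, t2 = tx("comp1_c0_seq1"), tx("comp1_c0_seq2")
        lab = labels_of(
            [t1, t2], [hit(t1.transcript_id, "NP_1", "proteome", "sense", scov=0.9)]
        )
        assert lab["comp1_c0_seq2"].category == "sense"

    def test_gene_without_sense_isoform_unchanged(self):
        t1, t2 = tx("comp1_c0_seq1"), tx("comp1_c0_seq2")
        labels = [
            CategoryLabel("comp1_c0_seq1", "unknown"),
            CategoryLabel("comp1_c0_seq2", "unknown"),
        ]
        assert propagate_sense_to_isoforms(labels, [t1, t2]) == labels

    def test_idempotent(self):
        t1, t2 = tx("comp1_c0_seq1"), tx("comp1_c0_seq2")
        labels = [
            CategoryLabel("comp1_c0_seq1", "sense"),
            CategoryLabel("comp1_c0_seq2", "unknown"),
        ]
        once = propagate_sense_to_isoforms(labels, [t1, t2])
        assert propagate_sense_to_isoforms(once, [t1, t2]) == once
        assert once[1].category == "sense"

    def test_propagation_beats_antisense_rule(self):
        # an isoform of a sense gene with an antisense protein hit stays sense
        t1, t2 = tx("comp1_c0_seq1"), tx("comp1_c0_seq2")
        lab = labels_of(
            [t1, t2],
            [
                hit(t1.transcript_id, "NP_1", "proteome", "sense", scov=0.9),
                hit(t2.transcript_id, "NP_2", "proteome", "antisense", scov=0.9),
            ],
        )
        assert lab["comp1_c0_seq2"].category == "sense"


def brute_force_orf(seq, min_aa=30):
    """Independent oracle: enumerate every ATG, walk to the first in-frame stop."""
    seq = seq.upper()
    best = None
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        pos = start
        while pos + 3 <= len(seq):
            codon = seq[pos:pos + 3]
            if "N" not in codon and codon in STOPS and pos > start:
                aa = (pos - start) // 3
                if aa >= min_aa:
                    cand = (aa, start, pos + 3)
                    if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                        best = cand
                break
            pos += 3
    return best  # (aa_length, start, end) or None


class TestOrfFinder:
    def test_30_aa_boundary_accepted(self):
        seq = "ATG" + "GCT" * 29 + "TAA"
        assert len(seq) == 93
        has, call = find_putative_orfs(seq)
        assert has and call.aa_length == 30
        assert call.start == 0 and call.end == 93

    def test_29_aa_boundary_rejected(self):
        seq = "ATG" + "GCT" * 28 + "TAA"
        has, call = find_putative_orfs(seq)
        assert not has and call is None

    def test_no_atg(self):
        assert find_putative_orfs("CCGTTT" * 60) == (False, None)

    def test_codons_with_n_never_start_or_stop(self):
        # ANG is not a start; TNA is not a stop, so the ORF runs through it
        seq = "ANG" + "GCT" * 40 + "TAA"
        has, call = find_putative_orfs(seq)
        assert not has
        seq = "ATG" + "GCT" * 15 + "TNA" + "GCT" * 15 + "TAA"
        has, call = find_putative_orfs(seq)
        assert has and call.aa_length == 32

    def test_longest_then_leftmost_tiebreak(self):
        orf_a = "ATG" + "GCT" * 35 + "TAA"  # 36 aa, frame 0 at 0
        orf_b = "ATG" + "GCA" * 35 + "TAA"  # same length, later
        seq = orf_a + "CC" + orf_b
        has, call = find_putative_orfs(seq)
        assert has and call.start == 0 and call.aa_length == 36

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(60, 400))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=n))
            has, call = find_putative_orfs(seq)
            oracle = brute_force_orf(seq)
            assert has == (oracle is not None)
            if oracle is not None:
                assert (call.aa_length, call.start, call.end) == oracle


class TestSummaries:
    def test_counts_percentages_mean_lengths(self):
        ts = [
            tx("comp1_c0_seq1", 100),
            tx("comp2_c0_seq1", 200),
            tx("comp3_c0_seq1", 300),
            tx("comp4_c0_seq1", 400),
        ]
        labels = [
            CategoryLabel("comp1_c0_seq1", "sense"),
            CategoryLabel("comp2_c0_seq1", "sense"),
            CategoryLabel("comp3_c0_seq1", "sense"),
            CategoryLabel("comp4_c0_seq1", "unknown"),
        ]
        table = summarize_categories(labels, ts).set_index("category")
        assert table.loc["sense", "count"] == 3
        assert table.loc["sense", "percent"] == 75.0
        assert table.loc["sense", "mean_length_bp"] == 200
        assert table.loc["total", "count"] == 4

    def test_subset_percentages_relative_to_subset(self):
        ts = [tx(f"comp{i}_c0_seq1", 100) for i in range(1, 5)]
        labels = [CategoryLabel(t.transcript_id, "sense") for t in ts[:3]] + [
            CategoryLabel(ts[3].transcript_id, "unknown")
        ]
        sub = summarize_categories(labels, ts, subset=[ts[0].transcript_id,
                                                       ts[3].transcript_id])
        sub = sub.set_index("category")
        assert sub.loc["sense", "percent"] == 50.0
        assert sub.loc["total", "count"] == 2

    def test_empty_subset_no_division_error(self):
        ts = [tx("comp1_c0_seq1")]
        labels = [CategoryLabel("comp1_c0_seq1", "sense")]
        table = summarize_categories(labels, ts, subset=[])
        assert (table["count"] == 0).all()

    def test_single_category_is_100pct(self):
        ts = [tx("comp1_c0_seq1"), tx("comp2_c0_seq1")]
        labels = [CategoryLabel(t.transcript_id, "lncRNA") for t in ts]
        table = summarize_categories(labels, ts).set_index("category")
        assert table.loc["lncRNA", "percent"] == 100.0


class TestPartitionProperties:
    def test_every_transcript_gets_exactly_one_category(self, small_catalogue):
        _, cat = small_catalogue
        for sp in ("Nv", "Ng"):
            labels = classify_transcripts(cat.transcripts[sp], cat.alignments[sp])
            assert len(labels) == len(cat.transcripts[sp])
            ids = [l.transcript_id for l in labels]
            assert ids == [t.transcript_id for t in cat.transcripts[sp]]

    def test_sense_dominance_over_later_rules(self, small_catalogue):
        # any transcript with a qualifying sense hit (or a sense gene-mate)
        # is never labelled antisense or lncRNA
        _, cat = small_catalogue
        for sp in ("Nv", "Ng"):
            labels = {
                l.transcript_id: l
                for l in classify_transcripts(cat.transcripts[sp], cat.alignments[sp])
            }
            gene_of = {t.transcript_id: t.gene_id for t in cat.transcripts[sp]}
            sense_genes = {
                gene_of[t] for t, l in labels.items() if l.category == "sense"
            }
            for t, l in labels.items():
                if gene_of[t] in sense_genes:
                    assert l.category == "sense"
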