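import math

import numpy as np
import pandas as pd
import pytest

from strandex.classify import CategoryLabel, classify_transcripts
from strandex.compare import (
    HomologyMap,
    antisense_to_panel,
    compare_transcriptomes,
    find_opposing_genes,
    known_gene_panel,
    map_best_hits,
    naive_interspecies_de,
)
from strandex.de import DifferentialExpressionModel
from strandex.io import AlignmentHit, CountMatrix, SampleMeta
from strandex.simulate import SimConfig, generate_catalogue, generate_counts


def hit(q, s, ev=1e-30, bs=100.0, db="proteome"):
    return AlignmentHit(q, s, db, "sense", 0.5, 0.7, 95.0, ev, bs)


def called_frame(rows):
    """rows: (transcript_id, contrast, log2fc, direction)"""
    return pd.DataFrame(
        [
            {"transcript_id": t, "contrast": c, "log2fc": l, "pvalue": 0.001,
             "fdr": 0.01 if d != "ns" else 0.9, "direction": d}
            for t, c, l, d in rows
        ]
    )


class TestBestHitMapping:
    def test_lowest_evalue_wins(self):
        hm = map_best_hits({"Nv": [hit("comp1_c0_seq1", "NP_b", ev=1e-10),
                                   hit("comp1_c0_seq1", "NP_a", ev=1e-50)],
                            "Ng": []})
        assert hm.forward["Nv"]["comp1_c0_seq1"] == "NP_a"

    def test_no_proteome_hit_absent(self):
        hm = map_best_hits({"Nv": [hit("comp1_c0_seq1", "chr1", db="genome")],
                            "Ng": []})
        assert "comp1_c0_seq1" not in hm.forward["Nv"]

    def test_full_tie_breaks_to_smaller_subject(self):
        hm = map_best_hits({"Nv": [hit("comp1_c0_seq1", "NP_b"),
                                   hit("comp1_c0_seq1", "NP_a")],
                            "Ng": []})
        assert hm.forward["Nv"]["comp1_c0_seq1"] == "NP_a"

    def test_inverse_index_consistent(self):
        hm = map_best_hits({"Nv": [hit("comp1_c0_seq1", "NP_a")],
                            "Ng": [hit("comp9_c0_seq1", "NP_a")]})
        assert hm.transcripts_of("NP_a", "Nv") == {"comp1_c0_seq1"}
        assert hm.transcripts_of("NP_a", "Ng") == {"comp9_c0_seq1"}


class TestSharedUnique:
    def test_example_counts(self):
        hm = HomologyMap(forward={
            "Nv": {"a": "p1", "b": "p2"},
            "Ng": {"c": "p2", "d": "p3"},
        })
        out = compare_transcriptomes(hm)
        assert (out["shared"], out["unique_Nv"], out["unique_Ng"]) == (1, 1, 1)

    def test_identical_maps_have_no_unique(self):
        hm = HomologyMap(forward={"Nv": {"a": "p1"}, "Ng": {"b": "p1"}})
        out = compare_transcriptomes(hm)
        assert out["shared"] == 1 and out["unique_Nv"] == out["unique_Ng"] == 0

    def test_partition_identity(self, small_catalogue):
        _, cat = small_catalogue
        hm = map_best_hits(cat.alignments)
        out = compare_transcriptomes(hm)
        union = hm.proteins("Nv") | hm.proteins("Ng")
        assert out["shared"] + out["unique_Nv"] + out["unique_Ng"] == len(union)

    def test_de_universe_restricts(self):
        hm = HomologyMap(forward={
            "Nv": {"a": "p1", "b": "p2"}, "Ng": {"c": "p1", "d": "p2"},
        })
        out = compare_transcriptomes(hm, universe="de_sets",
                                     de_sets={"Nv": {"a"}, "Ng": {"c", "d"}})
        assert out["shared"] == 1 and out["unique_Ng"] == 1


class TestOpposingGenes:
    def make(self):
        hm = HomologyMap(forward={"Nv": {"nv1": "p1", "nv2": "p2"},
                                  "Ng": {"ng1": "p1", "ng2": "p2"}})
        return hm

    def test_same_timepoint_opposite_qualifies(self):
        hm = self.make()
        de = {
            "Nv": called_frame([("nv1", "h4_vs_naive", 2.0, "up")]),
            "Ng": called_frame([("ng1", "h4_vs_naive", -1.5, "down")]),
        }
        out = find_opposing_genes(de, hm)
        assert set(out["protein_id"]) == {"p1"}

    def test_different_timepoints_do_not_qualify_by_default(self):
        hm = self.make()
        de = {
            "Nv": called_frame([("nv1", "h0_vs_naive", 2.0, "up")]),
            "Ng": called_frame([("ng1", "h24_vs_naive", 2.0, "up")]),
        }
        assert len(find_opposing_genes(de, hm)) == 0
        de["Ng"] = called_frame([("ng1", "h24_vs_naive", -2.0, "down")])
        assert len(find_opposing_genes(de, hm)) == 0
        # the any-time-point variant accepts the second case
        out = find_opposing_genes(de, hm, same_timepoint=False)
        assert set(out["protein_id"]) == {"p1"}

    def test_symmetric_under_species_swap(self):
        hm = self.make()
        de = {
            "Nv": called_frame([("nv1", "h4_vs_naive", 2.0, "up"),
                                ("nv2", "h0_vs_naive", -1.0, "down")]),
            "Ng": called_frame([("ng1", "h4_vs_naive", -1.5, "down"),
                                ("ng2", "h0_vs_naive", 1.0, "up")]),
        }
        a = find_opposing_genes(de, hm)
        swapped = {
            "Nv": de["Ng"].assign(),
            "Ng": de["Nv"].assign(),
        }
        hm_sw = HomologyMap(forward={"Nv": hm.forward["Ng"],
                                     "Ng": hm.forward["Nv"]})
        b = find_opposing_genes(swapped, hm_sw)
        assert set(a["protein_id"]) == set(b["protein_id"]) == {"p1", "p2"}


class TestPanel:
    def setup_objects(self):
        hm = HomologyMap(forward={"Nv": {"nv1": "p1"}, "Ng": {"ng1": "p1"}})
        labels = {"Nv": [], "Ng": []}
        return hm, labels

    def test_single_species_de_cell(self):
        hm, labels = self.setup_objects()
        de = {
            "Nv": called_frame([("nv1", "h4_vs_naive", 2.0, "up")]),
            "Ng": called_frame([("ng1", "h4_vs_naive", 0.5, "ns")]),
        }
        table = known_gene_panel([("p1", "geneA")], de, labels, hm)
        row = table.iloc[0]
        assert row["Nv_h4"] == "2.00*"
        assert row["Nv_h0"] == "ns" and row["Ng_h4"] == "ns"

    def test_display_threshold_marks_only_large_changes(self):
        hm, labels = self.setup_objects()
        de = {
            "Nv": called_frame([("nv1", "h0_vs_naive", 1.2, "up")]),
            "Ng": called_frame([]),
        }
        table = known_gene_panel([("p1", "geneA")], de, labels, hm)
        assert table.iloc[0]["Nv_h0"] == "1.20"  # no asterisk below 1.5

    def test_multiple_de_transcripts_get_numbered_rows(self):
        hm = HomologyMap(forward={"Nv": {"nv1": "p1", "nv2": "p1"},
                                  "Ng": {"ng1": "p1"}})
        de = {
            "Nv": called_frame([("nv1", "h0_vs_naive", 2.0, "up"),
                                ("nv2", "h4_vs_naive", -2.0, "down")]),
            "Ng": called_frame([]),
        }
        table = known_gene_panel([("p1", "geneA")], de, {"Nv": [], "Ng": []}, hm)
        assert list(table["gene_symbol"]) == ["geneA (1)", "geneA (2)"]

    def test_absent_gene_warns_and_is_all_ns(self, caplog):
        hm, labels = self.setup_objects()
        de = {"Nv": called_frame([]), "Ng": called_frame([])}
        with caplog.at_level("WARNING"):
            table = known_gene_panel([("p_missing", "geneX")], de, labels, hm)
        assert "absent" in caplog.text
        row = table.iloc[0]
        assert all(row[c] == "ns" for c in ("Nv_h0", "Nv_h4", "Nv_h24",
                                            "Ng_h0", "Ng_h4", "Ng_h24"))


class TestAntisenseToPanel:
    def test_antisense_via_sense_transcript_maps_to_gene(self):
        hm = HomologyMap(forward={"Nv": {"sense1": "p1"}, "Ng": {}})
        labels = {
            "Nv": [CategoryLabel("anti1", "antisense_to_sense",
                                 evidence=("sense1",))],
            "Ng": [],
        }
        out = antisense_to_panel(labels, [("p1", "geneA")], hm)
        row = out.set_index("protein_id").loc["p1"]
        assert row["antisense_Nv"] and not row["antisense_Ng"]
        assert row["subtypes_Nv"] == "antisense_to_sense"

    def test_direct_protein_evidence(self):
        hm = HomologyMap(forward={"Nv": {}, "Ng": {}})
        labels = {
            "Nv": [],
            "Ng": [CategoryLabel("anti1", "antisense_to_protein",
                                 evidence=("p1",))],
        }
        out = antisense_to_panel(labels, [("p1", "geneA")], hm)
        assert out.iloc[0]["antisense_Ng"]
        assert out.attrs["counts"] == {"any": 1, "only_Nv": 0, "only_Ng": 1,
                                       "both": 0}

    def test_no_antisense_labels_no_flags(self):
        hm = HomologyMap(forward={"Nv": {"s": "p1"}, "Ng": {}})
        labels = {"Nv": [CategoryLabel("s", "sense")], "Ng": []}
        out = antisense_to_panel(labels, [("p1", "geneA")], hm)
        assert not out.iloc[0]["antisense_Nv"]

    def test_truth_recovery_on_synthetic_catalogue(self, small_catalogue):
        cfg, cat = small_catalogue
        labels = {
            sp: classify_transcripts(cat.transcripts[sp], cat.alignments[sp])
            for sp in ("Nv", "Ng")
        }
        hm = map_best_hits(cat.alignments)
        out = antisense_to_panel(labels, cat.panel, hm).set_index("protein_id")
        truth_flags = {
            (t.homolog_protein_id, t.species)
            for t in cat.truth
            if t.true_category in ("antisense_to_sense", "antisense_to_both")
            and t.homolog_protein_id in {p for p, _ in cat.panel}
        }
        for pid, _ in cat.panel:
            for sp in ("Nv", "Ng"):
                assert out.loc[pid, f"antisense_{sp}"] == (
                    (pid, sp) in truth_flags
                )


class TestNaiveInterspecies:
    def make_counts(self, nv_rows, ng_rows):
        metas = {}
        counts = {}
        for sp, rows in (("Nv", nv_rows), ("Ng", ng_rows)):
            ms = [SampleMeta(f"{sp}_{g}_r{r}", sp, g, r)
                  for g in ("naive", "h0", "h4", "h24") for r in (1, 2, 3)]
            df = pd.DataFrame(rows, index=[m.sample_id for m in ms]).T
            counts[sp] = CountMatrix(df)
            metas[sp] = ms
        return counts, metas

    def test_one_to_many_excluded_and_signal_detected(self):
        rng = np.random.default_rng(0)
        base = lambda level: list(rng.poisson(level, 12))
        nv = {"nv1": base(100), "nv2a": base(100), "nv2b": base(100),
              "nvbg": base(5000)}
        ng = {"ng1": base(400), "ng2": base(100), "ngbg": base(5000)}
        counts, metas = self.make_counts(nv, ng)
        hm = HomologyMap(forward={
            "Nv": {"nv1": "p1", "nv2a": "p2", "nv2b": "p2", "nvbg": "pbg"},
            "Ng": {"ng1": "p1", "ng2": "p2", "ngbg": "pbg"},
        })
        res = naive_interspecies_de(counts, metas, hm)
        # p2 has two Nv transcripts: not 1:1, excluded
        assert set(res["transcript_id"]) == {"p1", "pbg"}
        row = res.set_index("transcript_id").loc["p1"]
        assert row["direction"] != "ns" and abs(row["log2fc"]) > 1.0

    def test_empty_comparable_set_warns(self, caplog):
        counts, metas = self.make_counts({"nv1": [10] * 12}, {"ng1": [10] * 12})
        hm = HomologyMap(forward={"Nv": {"nv1": "p1"}, "Ng": {"ng1": "p2"}})
        with caplog.at_level("WARNING"):
            res = naive_interspecies_de(counts, metas, hm)
        assert len(res) == 0 and "empty comparable" in caplog.text


class TestTruthRecoveryStrongSignal:
    def test_opposing_genes_recovered_exactly(self):
        cfg = SimConfig(seed=2015, n_sense=80, n_antisense_to_protein=4,
                        n_antisense_to_sense=4, n_antisense_to_both=2,
                        n_lncrna=6, n_unknown=5, n_panel_genes=8,
                        n_panel_antisense=3, n_opposing=5, fraction_de=0.0,
                        lfc_min=2.0, lfc_max=3.0,
                        baseline_log_mean=math.log(800), baseline_log_sd=0.5,
                        dispersion=0.02)
        cat = generate_catalogue(cfg)
        counts, metas = generate_counts(cat, cfg)
        de = {
            sp: DifferentialExpressionModel(counts[sp], metas[sp]).fit().frame
            for sp in ("Nv", "Ng")
        }
        hm = map_best_hits(cat.alignments)
        out = find_opposing_genes(de, hm)
        planted = {t.homolog_protein_id for t in cat.truth if t.opposing_flag}
        assert len(planted) == 5
        assert set(out["protein_id"]) == planted
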