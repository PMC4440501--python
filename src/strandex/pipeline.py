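"""End-to-end orchestration: classify -> filter -> DE -> compare -> enrich -> report.

A :class:`PipelineConfig` names every input file (per species), the thresholds
and significance levels, and an output directory; :func:`run_pipeline` executes
the stages in order and writes the study-style report tables plus a manifest
recording the config hash, seed and per-stage record counts, so every reported
total is auditable from the manifest alone.  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as _io
from .classify import (
    Thresholds,
    apply_length_filter,
    classify_transcripts,
    labels_to_frame,
    summarize_categories,
)
from .compare import (
    antisense_to_panel,
    compare_transcriptomes,
    find_opposing_genes,
    known_gene_panel,
    map_best_hits,
    naive_interspecies_de,
)
from .de import CONTRASTS, DifferentialExpressionModel, de_sets, filter_transcripts
from .enrich import fisher_enrichment, summarize_enrichment
from .report import de_membership_table, single_timepoint_fraction

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger(__name__)

SPECIES = ("Nv", "Ng")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Paths and parameters driving a full two-species run."""

    fasta: dict[str, str]
    alignments: dict[str, str]
    counts: dict[str, str]
    sample_meta: dict[str, str]
    go_map: str
    panel: str
    outdir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    de_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    seed: int = 0
    min_cpm_samples: int = 3

    def __post_init__(self):
        if not (0.0 < self.de_alpha < 1.0 and 0.0 < self.enrichment_alpha < 1.0):
            raise ValueError("significance levels must lie in (0, 1)")

    def validate_paths(self) -> None:
        missing = []
        for group in (self.fasta, self.alignments, self.counts, self.sample_meta):
            for sp in SPECIES:
                if sp not in group:
                    raise StageError(f"config: missing species {sp!r} entry")
                if not Path(group[sp]).exists():
                    missing.append(group[sp])
        for p in (self.go_map, self.panel):
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise StageError(f"config: input path(s) do not exist: {missing}")

    def content_hash(self) -> str:
        payload = {
            "fasta": self.fasta,
            "alignments": self.alignments,
            "counts": self.counts,
            "sample_meta": self.sample_meta,
            "go_map": self.go_map,
            "panel": self.panel,
            "thresholds": asdict(self.thresholds),
            "de_alpha": self.de_alpha,
            "enrichment_alpha": self.enrichment_alpha,
            "seed": self.seed,
            "min_cpm_samples": self.min_cpm_samples,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = Thresholds(**th)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns in-memory results."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }

    transcripts, labels, hits = {}, {}, {}
    counts, metas = {}, {}
    kept = {}
    de_results = {}

    for sp in SPECIES:
        # ---- load + length filter + classification
        tx = _io.read_fasta(config.fasta[sp])
        tx = apply_length_filter(tx, config.thresholds.min_transcript_len)
        sp_hits = _io.read_alignment_table(config.alignments[sp])
        known = {t.transcript_id for t in tx}
        sp_hits = [h for h in sp_hits if h.query_id in known]
        lab = classify_transcripts(tx, sp_hits, config.thresholds)
        transcripts[sp], labels[sp], hits[sp] = tx, lab, sp_hits
        labels_to_frame(lab).to_csv(
            outdir / f"labels_{sp}.tsv", sep="\t", index=False
        )
        manifest["stages"][f"classify_{sp}"] = {
            "transcripts": len(tx),
            "alignments": len(sp_hits),
        }

        # ---- counts + expression filter
        cm, sm = _io.read_count_data(config.counts[sp], config.sample_meta[sp])
        lengths = {t.transcript_id: t.length_bp for t in tx}
        # transcripts in the counts but dropped by the length filter are gone
        present = [t for t in cm.transcript_ids if t in lengths]
        cm = cm.subset(transcript_ids=present)
        kept[sp] = filter_transcripts(
            cm,
            lengths,
            min_len=config.thresholds.min_transcript_len,
            min_samples=config.min_cpm_samples,
        )
        counts[sp] = cm.subset(transcript_ids=kept[sp])
        metas[sp] = sm
        manifest["stages"][f"filter_{sp}"] = {
            "input": len(present),
            "kept": len(kept[sp]),
        }

        # ---- differential expression (three contrasts vs naive)
        model = DifferentialExpressionModel(
            counts[sp], metas[sp], alpha=config.de_alpha
        )
        res = model.fit(CONTRASTS)
        de_results[sp] = res
        res.frame.to_csv(outdir / f"de_{sp}.tsv", sep="\t", index=False)
        manifest["stages"][f"de_{sp}"] = {
            "transcripts": len(counts[sp].transcript_ids),
            "n_de_union": len(
                set().union(*res.de_sets().values())
            ),
        }

        # ---- Table-1-style summaries (total + DE union + per time point)
        summaries = {"total": summarize_categories(lab, tx)}
        sets = res.de_sets()
        union = sorted(set().union(*sets.values()))
        summaries["de_total"] = summarize_categories(lab, tx, subset=union)
        for contrast in CONTRASTS:
            tp = contrast.split("_")[0]
            summaries[f"de_{tp}"] = summarize_categories(
                lab, tx, subset=sorted(sets[contrast])
            )
        table1 = pd.concat(
            [df.assign(block=name) for name, df in summaries.items()],
            ignore_index=True,
        )[["block", "category", "count", "percent", "mean_length_bp"]]
        table1.to_csv(outdir / f"category_summary_{sp}.tsv", sep="\t", index=False)

        # ---- Figure-2-style membership and single-time-point fractions
        up = res.de_sets("up")
        down = res.de_sets("down")
        de_membership_table(up, down).to_csv(
            outdir / f"de_membership_{sp}.tsv", sep="\t", index=False
        )
        single_timepoint_fraction(sets).to_csv(
            outdir / f"de_timepoint_multiplicity_{sp}.tsv", sep="\t", index=False
        )

    # ---- cross-species stages
    hmap = map_best_hits(hits)
    shared_all = compare_transcriptomes(hmap, universe="all")
    de_union = {
        sp: set().union(*de_results[sp].de_sets().values()) for sp in SPECIES
    }
    shared_de = compare_transcriptomes(hmap, universe="de_sets", de_sets=de_union)
    pd.DataFrame(
        [
            {k: shared_all[k] for k in ("shared", "unique_Ng", "unique_Nv")}
            | {"universe": "all"},
            {k: shared_de[k] for k in ("shared", "unique_Ng", "unique_Nv")}
            | {"universe": "de"},
        ]
    ).to_csv(outdir / "shared_unique.tsv", sep="\t", index=False)
    manifest["stages"]["compare"] = {
        "shared_all": shared_all["shared"],
        "shared_de": shared_de["shared"],
    }

    de_frames = {sp: de_results[sp].frame for sp in SPECIES}
    opposing = find_opposing_genes(de_frames, hmap)
    opposing.to_csv(outdir / "opposing_genes.tsv", sep="\t", index=False)
    manifest["stages"]["opposing"] = {
        "genes": int(opposing["protein_id"].nunique()) if len(opposing) else 0
    }

    panel = _io.read_panel(config.panel)
    panel_table = known_gene_panel(panel, de_frames, labels, hmap)
    panel_table.to_csv(outdir / "panel.tsv", sep="\t", index=False)
    anti_panel = antisense_to_panel(labels, panel, hmap)
    anti_panel.to_csv(outdir / "panel_antisense.tsv", sep="\t", index=False)
    manifest["stages"]["panel"] = {
        "genes": len(panel),
        "with_antisense": anti_panel.attrs.get("counts", {}).get("any", 0),
    }

    naive_de = naive_interspecies_de(counts, metas, hmap, alpha=config.de_alpha)
    naive_de.to_csv(outdir / "naive_interspecies_de.tsv", sep="\t", index=False)
    manifest["stages"]["naive_interspecies"] = {
        "comparable": len(naive_de),
        "significant": int((naive_de["direction"] != "ns").sum())
        if len(naive_de)
        else 0,
    }

    # ---- GO enrichment per (species, time point, direction)
    go = _io.read_go_map(config.go_map)
    sense_proteins = {
        sp: {
            hmap.forward[sp][l.transcript_id]
            for l in labels[sp]
            if l.category == "sense" and l.transcript_id in hmap.forward[sp]
        }
        for sp in SPECIES
    }
    cells = {}
    for sp in SPECIES:
        for direction in ("up", "down"):
            sets = de_results[sp].de_sets(direction)
            for contrast in CONTRASTS:
                tp = contrast.split("_")[0]
                de_prot = {
                    hmap.forward[sp][t]
                    for t in sets[contrast]
                    if t in hmap.forward[sp]
                } & sense_proteins[sp]
                cells[(sp, tp, direction)] = fisher_enrichment(
                    de_prot, sense_proteins[sp], go,
                    alpha=config.enrichment_alpha,
                )
    enr = summarize_enrichment(cells, alpha=config.enrichment_alpha)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    manifest["stages"]["enrichment"] = {"significant_cells": len(enr)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "labels": labels,
        "de": de_results,
        "hmap": hmap,
        "shared_all": shared_all,
        "shared_de": shared_de,
        "opposing": opposing,
        "panel_table": panel_table,
        "panel_antisense": anti_panel,
        "naive_de": naive_de,
        "enrichment": enr,
        "manifest": manifest,
    }
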