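"""Two-species synthetic input generator with a known truth layer.

Emulates the structure of a stranded two-species head-transcriptome study so
that every downstream stage (classification, filtering, DE, cross-species
comparison, enrichment) can be exercised against ground truth without any
sequencing data: a Trinity-style transcript catalogue with isoform structure,
strand-aware alignment tables consistent with each transcript's true category
under the classifier's thresholds, NB-distributed counts over a
4-group x 3-replicate design per species with planted per-time-point log2 fold
changes (including opposing-direction genes), and GO annotations with planted
enriched terms.

One global seed drives independent per-purpose streams (catalogue, counts,
GO), so each stage can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignmentHit,
    CountMatrix,
    GOAnnotation,
    SampleMeta,
    TranscriptRecord,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SyntheticCatalogue",
    "generate_catalogue",
    "generate_counts",
    "generate_go_annotations",
    "write_truth",
    "read_truth",
    "write_bundle",
]

SPECIES = ("Nv", "Ng")
TIME_POINTS = ("h0", "h4", "h24")
CATEGORY_FIELDS = (
    "n_sense",
    "n_antisense_to_protein",
    "n_antisense_to_sense",
    "n_antisense_to_both",
    "n_lncrna",
    "n_unknown",
)
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Category gene counts are per species.  Defaults are desk-scale but keep
    the study's composition: a sense-dominated catalogue (~70% of genes),
    few antisense genes, a 12-sample design per species (naive + three
    post-conditioning time points x 3 replicates), NB counts with a
    log-normal baseline and biological CV ~ sqrt(0.1), and a replicate block
    effect of s.d. 0.1 on the log scale.
    """

    seed: int
    # catalogue composition (genes per category per species)
    n_sense: int = 150
    n_antisense_to_protein: int = 12
    n_antisense_to_sense: int = 10
    n_antisense_to_both: int = 5
    n_lncrna: int = 20
    n_unknown: int = 15
    # isoform structure (sense genes only; other categories are single-isoform)
    isoform_singleton_prob: float = 0.747
    max_isoforms: int = 4
    # transcript lengths (log-normal, clipped at the 200 bp assembly floor)
    length_log_mean: float = math.log(600.0)
    length_log_sd: float = 0.45
    # fraction of nr-rescued sense genes (proteome hit < 60%, nr hit > 60%)
    nr_rescue_frac: float = 0.05
    # fraction of lncRNA / unknown transcripts carrying a putative ORF
    orf_frac_noncoding: float = 0.25
    # minimum residues of embedded ORFs (matches the classifier's default)
    orf_min_aa: int = 30
    # counts
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.2
    dispersion: float = 0.1
    dispersion_slope: float = 0.0  # phi = dispersion + slope / baseline mean
    replicate_sd: float = 0.1
    # planted differential expression
    fraction_de: float = 0.1
    lfc_min: float = 1.0
    lfc_max: float = 3.0
    n_opposing: int = 5
    # cross-species structure
    shared_homolog_frac: float = 0.8
    n_panel_genes: int = 20
    n_panel_antisense: int = 6
    # GO annotations
    go_n_terms: int = 40
    go_density: float = 0.08
    go_n_enriched: int = 3
    go_enriched_de_frac: float = 0.8
    go_background_frac: float = 0.05
    # alignment placement: fraction of qualifying hits placed just above the
    # coverage cut-offs (identity then sits exactly at the inclusive 95 bound)
    near_threshold_frac: float = 0.1
    near_threshold_margin: float = 0.005

    def __post_init__(self):
        for name in (
            "isoform_singleton_prob", "nr_rescue_frac", "orf_frac_noncoding",
            "fraction_de", "shared_homolog_frac", "go_density",
            "go_enriched_de_frac", "go_background_frac", "near_threshold_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in CATEGORY_FIELDS + (
            "n_opposing", "n_panel_genes", "n_panel_antisense",
            "go_n_terms", "go_n_enriched",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        needs_sense = (
            self.n_antisense_to_sense + self.n_antisense_to_both
        )
        if needs_sense > 0 and self.n_sense == 0:
            raise ValueError(
                "antisense-to-sense categories require at least one sense gene"
            )
        n_shared = int(round(self.shared_homolog_frac * self.n_sense))
        if self.n_panel_genes + self.n_opposing > n_shared:
            raise ValueError(
                f"panel ({self.n_panel_genes}) + opposing ({self.n_opposing}) "
                f"genes exceed the {n_shared} shared sense genes"
            )
        if self.n_panel_antisense > self.n_panel_genes:
            raise ValueError("n_panel_antisense exceeds n_panel_genes")
        if self.n_panel_antisense:
            per_species_need = 1 + (self.n_panel_antisense - 1 + 1) // 2
            if per_species_need > self.n_antisense_to_sense:
                raise ValueError(
                    "n_antisense_to_sense too small for the requested "
                    "panel-antisense placement"
                )
        if self.go_n_enriched > self.go_n_terms:
            raise ValueError("go_n_enriched exceeds go_n_terms")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic transcript."""

    transcript_id: str
    species: str
    true_category: str
    true_has_orf: bool
    homolog_protein_id: Optional[str]
    planted_log2fc: dict[str, float]
    opposing_flag: bool = False
    enriched_term_member: bool = False

    def __post_init__(self):
        if set(self.planted_log2fc) != set(TIME_POINTS):
            raise ValueError(
                "planted_log2fc must be defined for exactly h0, h4, h24"
            )


@dataclass
class SyntheticCatalogue:
    """Transcripts, alignments, truth and the memory-gene panel, per species."""

    transcripts: dict[str, list[TranscriptRecord]]
    alignments: dict[str, list[AlignmentHit]]
    truth: list[TruthRecord]
    panel: list[tuple[str, str]]

    def truth_by_species(self, species: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.species == species]


def _rng(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(purpose,)))


def _seq_without_atg(rng: np.random.Generator, n: int) -> str:
    """Random ACGT sequence containing no ATG substring (hence no ORF in any frame)."""
    chars = []
    for _ in range(n):
        if len(chars) >= 2 and chars[-2] == "A" and chars[-1] == "T":
            chars.append("ACT"[rng.integers(3)])
        else:
            chars.append("ACGT"[rng.integers(4)])
    return "".join(chars)


def _embed_orf(rng: np.random.Generator, background: str, min_aa: int) -> str:
    """Overwrite a stretch of the background with ATG + non-stop codons + TAA."""
    aa = int(rng.integers(min_aa, min_aa + 40))
    orf = "ATG" + "".join(
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(aa - 1)
    ) + "TAA"
    if len(orf) > len(background):
        background = background + _seq_without_atg(rng, len(orf) - len(background) + 6)
    start = int(rng.integers(0, len(background) - len(orf) + 1))
    return background[:start] + orf + background[start + len(orf):]


def _length(rng: np.random.Generator, cfg: SimConfig) -> int:
    L = int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd)))
    return max(L, 210)


def _coverage(rng, cfg: SimConfig, cut: float, lo: float, hi: float) -> float:
    """A qualifying coverage: usually well above the cut, sometimes just above."""
    if rng.random() < cfg.near_threshold_frac:
        return cut + cfg.near_threshold_margin
    return float(rng.uniform(lo, hi))


def _identity(rng, cfg: SimConfig, lo: float = 95.5, hi: float = 99.5) -> float:
    if rng.random() < cfg.near_threshold_frac:
        return 95.0  # inclusive boundary
    return float(round(rng.uniform(lo, hi), 2))


def _pick_target(rng, proteins: list[str], n_panel: int, j: int) -> str:
    """A non-panel protein for antisense targeting (standalone id if none exist)."""
    if len(proteins) > n_panel:
        return proteins[int(rng.integers(n_panel, len(proteins)))]
    return f"NP_9{j:05d}"


def _hit(rng, query_id, subject_id, subject_db, orientation, qcov, scov, ident):
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        subject_db=subject_db,
        orientation=orientation,
        query_coverage=round(float(qcov), 6),
        subject_coverage=round(float(scov), 6),
        identity_pct=float(ident),
        evalue=float(f"{10.0 ** -rng.uniform(20, 120):.3g}"),
        bitscore=float(round(rng.uniform(100, 900), 1)),
    )


def generate_catalogue(config: SimConfig) -> SyntheticCatalogue:
    """Generate the two-species transcript catalogue with consistent alignments.

    Every emitted alignment set satisfies (strictly, never at the boundary for
    coverages) the classification rule of its transcript's true category, and
    no disqualifying hit crosses an earlier rule's bar, so a classifier run on
    the noise-free output must recover the truth labels exactly.
    """
    cfg = config
    rng = _rng(cfg.seed, 0)

    n_shared = int(round(cfg.shared_homolog_frac * cfg.n_sense))
    shared_proteins = [f"NP_{i:06d}" for i in range(n_shared)]
    unique_proteins = {
        "Nv": [f"NP_7{i:05d}" for i in range(cfg.n_sense - n_shared)],
        "Ng": [f"NP_8{i:05d}" for i in range(cfg.n_sense - n_shared)],
    }
    panel_proteins = shared_proteins[: cfg.n_panel_genes]
    panel = [(pid, f"mem-{j + 1}") for j, pid in enumerate(panel_proteins)]
    opposing_proteins = shared_proteins[
        cfg.n_panel_genes : cfg.n_panel_genes + cfg.n_opposing
    ]

    # deterministic placement of panel antisense transcripts:
    # the first flagged gene gets one in both species, then alternating
    panel_anti_species: dict[str, list[str]] = {sp: [] for sp in SPECIES}
    for k in range(cfg.n_panel_antisense):
        pid = panel_proteins[k]
        if k == 0:
            panel_anti_species["Nv"].append(pid)
            panel_anti_species["Ng"].append(pid)
        elif k % 2 == 1:
            panel_anti_species["Nv"].append(pid)
        else:
            panel_anti_species["Ng"].append(pid)

    # per (shared protein, time point) a shared DE direction, so random
    # planting never creates an accidental opposing-direction gene
    shared_sign = {
        (pid, tp): (1.0 if rng.random() < 0.5 else -1.0)
        for pid in shared_proteins
        for tp in TIME_POINTS
    }

    transcripts: dict[str, list[TranscriptRecord]] = {sp: [] for sp in SPECIES}
    alignments: dict[str, list[AlignmentHit]] = {sp: [] for sp in SPECIES}
    truth: list[TruthRecord] = []

    for sp in SPECIES:
        comp = 0
        proteins = shared_proteins + unique_proteins[sp]
        main_isoform_of: dict[str, str] = {}

        def new_gene() -> str:
            nonlocal comp
            comp += 1
            return f"comp{comp}_c0"

        def plant_lfc(pid: Optional[str]) -> dict[str, float]:
            out = {}
            for tp in TIME_POINTS:
                if rng.random() < cfg.fraction_de:
                    mag = float(rng.uniform(cfg.lfc_min, cfg.lfc_max))
                    if pid is not None and (pid, tp) in shared_sign:
                        out[tp] = shared_sign[(pid, tp)] * mag
                    else:
                        out[tp] = mag if rng.random() < 0.5 else -mag
                else:
                    out[tp] = 0.0
            return out

        # ---- sense genes
        for j, pid in enumerate(proteins):
            gene = new_gene()
            n_iso = 1
            if rng.random() >= cfg.isoform_singleton_prob:
                n_iso = 2 + int(rng.integers(0, cfg.max_isoforms - 1))
            nr_rescued = rng.random() < cfg.nr_rescue_frac
            for k in range(1, n_iso + 1):
                tid = f"{gene}_seq{k}"
                L = _length(rng, cfg)
                seq = _embed_orf(rng, _seq_without_atg(rng, L), cfg.orf_min_aa)
                transcripts[sp].append(TranscriptRecord(tid, seq))
                if k == 1:
                    main_isoform_of[pid] = tid
                    if nr_rescued:
                        # sub-bar proteome hit plus a qualifying nr hit
                        alignments[sp].append(_hit(
                            rng, tid, pid, "proteome", "sense",
                            rng.uniform(0.3, 0.9), rng.uniform(0.2, 0.55),
                            round(rng.uniform(80, 99), 2),
                        ))
                        alignments[sp].append(_hit(
                            rng, tid, f"nr_{pid}", "nr_protein", "sense",
                            rng.uniform(0.3, 0.9),
                            _coverage(rng, cfg, 0.60, 0.65, 0.95),
                            round(rng.uniform(80, 99), 2),
                        ))
                    else:
                        alignments[sp].append(_hit(
                            rng, tid, pid, "proteome", "sense",
                            rng.uniform(0.3, 0.9),
                            _coverage(rng, cfg, 0.60, 0.65, 0.95),
                            round(rng.uniform(80, 99), 2),
                        ))
                else:
                    # minor isoform: sub-bar proteome hit or none; rescued by
                    # isoform propagation
                    if rng.random() < 0.7:
                        alignments[sp].append(_hit(
                            rng, tid, pid, "proteome", "sense",
                            rng.uniform(0.2, 0.8), rng.uniform(0.1, 0.5),
                            round(rng.uniform(80, 99), 2),
                        ))
                truth.append(TruthRecord(
                    tid, sp, "sense", True, pid, plant_lfc(pid),
                ))

        # ---- antisense to a protein
        for j in range(cfg.n_antisense_to_protein):
            gene = new_gene()
            tid = f"{gene}_seq1"
            L = _length(rng, cfg)
            seq = _seq_without_atg(rng, L)
            transcripts[sp].append(TranscriptRecord(tid, seq))
            target = _pick_target(rng, proteins, cfg.n_panel_genes, j)
            alignments[sp].append(_hit(
                rng, tid, target, "proteome", "antisense",
                rng.uniform(0.3, 0.9),
                _coverage(rng, cfg, 0.50, 0.55, 0.90),
                round(rng.uniform(80, 99), 2),
            ))
            truth.append(TruthRecord(
                tid, sp, "antisense_to_protein", False, target,
                plant_lfc(None),
            ))

        # ---- antisense to a sense transcript
        anti_sense_targets = list(panel_anti_species[sp])
        pool = [p for p in proteins if p not in set(anti_sense_targets)]
        while len(anti_sense_targets) < cfg.n_antisense_to_sense:
            anti_sense_targets.append(pool[int(rng.integers(len(pool)))])
        for target in anti_sense_targets:
            gene = new_gene()
            tid = f"{gene}_seq1"
            L = _length(rng, cfg)
            seq = _seq_without_atg(rng, L)
            transcripts[sp].append(TranscriptRecord(tid, seq))
            alignments[sp].append(_hit(
                rng, tid, main_isoform_of[target], "sense_transcript",
                "antisense",
                _coverage(rng, cfg, 0.80, 0.85, 0.98),
                rng.uniform(0.3, 0.9),
                _identity(rng, cfg),
            ))
            truth.append(TruthRecord(
                tid, sp, "antisense_to_sense", False, target, plant_lfc(None),
            ))

        # ---- antisense to both (protein and sense transcript of one gene)
        for j in range(cfg.n_antisense_to_both):
            gene = new_gene()
            tid = f"{gene}_seq1"
            L = _length(rng, cfg)
            seq = _seq_without_atg(rng, L)
            transcripts[sp].append(TranscriptRecord(tid, seq))
            target = _pick_target(rng, proteins, cfg.n_panel_genes, j)
            alignments[sp].append(_hit(
                rng, tid, target, "proteome", "antisense",
                rng.uniform(0.3, 0.9),
                _coverage(rng, cfg, 0.50, 0.55, 0.90),
                round(rng.uniform(80, 99), 2),
            ))
            alignments[sp].append(_hit(
                rng, tid, main_isoform_of[target], "sense_transcript",
                "antisense",
                _coverage(rng, cfg, 0.80, 0.85, 0.98),
                rng.uniform(0.3, 0.9),
                _identity(rng, cfg),
            ))
            truth.append(TruthRecord(
                tid, sp, "antisense_to_both", False, target, plant_lfc(None),
            ))

        # ---- lncRNA: genome (or nt) hit only
        for j in range(cfg.n_lncrna):
            gene = new_gene()
            tid = f"{gene}_seq1"
            L = _length(rng, cfg)
            has_orf = rng.random() < cfg.orf_frac_noncoding
            seq = _seq_without_atg(rng, L)
            if has_orf:
                seq = _embed_orf(rng, seq, cfg.orf_min_aa)
            transcripts[sp].append(TranscriptRecord(tid, seq))
            db = "genome" if rng.random() < 0.7 else "nt"
            subject = (
                f"chr{1 + int(rng.integers(5))}" if db == "genome"
                else f"NT_{int(rng.integers(10 ** 6)):06d}"
            )
            alignments[sp].append(_hit(
                rng, tid, subject, db,
                "sense" if rng.random() < 0.5 else "antisense",
                _coverage(rng, cfg, 0.80, 0.85, 0.98),
                rng.uniform(0.01, 0.2),
                _identity(rng, cfg),
            ))
            truth.append(TruthRecord(
                tid, sp, "lncRNA", has_orf, None, plant_lfc(None),
            ))

        # ---- unknown: no qualifying hit anywhere
        for j in range(cfg.n_unknown):
            gene = new_gene()
            tid = f"{gene}_seq1"
            L = _length(rng, cfg)
            has_orf = rng.random() < cfg.orf_frac_noncoding
            seq = _seq_without_atg(rng, L)
            if has_orf:
                seq = _embed_orf(rng, seq, cfg.orf_min_aa)
            transcripts[sp].append(TranscriptRecord(tid, seq))
            r = rng.random()
            if r < 0.33:
                pass  # no hits at all
            elif r < 0.66:
                # sub-bar sense proteome hit (< 60%, and sense so the
                # antisense rule cannot fire)
                target = proteins[int(rng.integers(len(proteins)))]
                alignments[sp].append(_hit(
                    rng, tid, target, "proteome", "sense",
                    rng.uniform(0.2, 0.7), rng.uniform(0.1, 0.55),
                    round(rng.uniform(80, 99), 2),
                ))
            else:
                # genome hit failing coverage or identity
                if rng.random() < 0.5:
                    qcov, ident = rng.uniform(0.2, 0.75), _identity(rng, cfg)
                else:
                    qcov, ident = rng.uniform(0.85, 0.98), round(
                        rng.uniform(75, 94), 2
                    )
                alignments[sp].append(_hit(
                    rng, tid, f"chr{1 + int(rng.integers(5))}", "genome",
                    "sense", qcov, rng.uniform(0.01, 0.2), ident,
                ))
            truth.append(TruthRecord(
                tid, sp, "unknown", has_orf, None, plant_lfc(None),
            ))

    # ---- planted opposing-direction genes (main isoforms, same time point)
    by_tid = {(t.species, t.transcript_id): i for i, t in enumerate(truth)}
    main_of = {
        sp: {
            t.homolog_protein_id: t.transcript_id
            for t in truth
            if t.species == sp and t.true_category == "sense"
            and t.transcript_id.endswith("_seq1")
        }
        for sp in SPECIES
    }
    for pid in opposing_proteins:
        tp = TIME_POINTS[int(rng.integers(len(TIME_POINTS)))]
        mag = float(rng.uniform(max(cfg.lfc_min, 1.5), cfg.lfc_max))
        for sp, sign in (("Nv", 1.0), ("Ng", -1.0)):
            tid = main_of[sp][pid]
            i = by_tid[(sp, tid)]
            truth[i] = replace(
                truth[i],
                planted_log2fc={
                    t: (sign * mag if t == tp else 0.0) for t in TIME_POINTS
                },
                opposing_flag=True,
            )

    # ---- force panel genes to be DE so the panel table is populated
    for j, pid in enumerate(panel_proteins):
        if pid in opposing_proteins:
            continue
        tp = TIME_POINTS[j % 3]
        mag = float(rng.uniform(max(cfg.lfc_min, 1.5), cfg.lfc_max))
        sign = shared_sign[(pid, tp)]
        targets = (
            ("Nv",) if j % 3 == 0 else ("Ng",) if j % 3 == 1 else ("Nv", "Ng")
        )
        for sp in targets:
            tid = main_of[sp][pid]
            i = by_tid[(sp, tid)]
            lfc = dict(truth[i].planted_log2fc)
            lfc[tp] = sign * mag
            truth[i] = replace(truth[i], planted_log2fc=lfc)

    # ---- mark members of the planted enriched terms among DE homolog genes
    de_proteins = sorted(
        {
            t.homolog_protein_id
            for t in truth
            if t.true_category == "sense"
            and t.homolog_protein_id is not None
            and any(v != 0.0 for v in t.planted_log2fc.values())
        }
    )
    members = {
        pid for pid in de_proteins if rng.random() < cfg.go_enriched_de_frac
    }
    truth = [
        replace(t, enriched_term_member=t.homolog_protein_id in members)
        if t.homolog_protein_id is not None
        else t
        for t in truth
    ]

    return SyntheticCatalogue(
        transcripts=transcripts,
        alignments=alignments,
        truth=truth,
        panel=panel,
    )


def generate_counts(
    catalogue_or_truth,
    config: SimConfig,
) -> tuple[dict[str, CountMatrix], dict[str, list[SampleMeta]]]:
    """NB counts per species over the 4-group x 3-replicate design.

    log mean = log baseline + planted_log2fc * log 2 (at flagged time points)
    + replicate effect; the dispersion is constant or linear in 1/mean;
    everything is reproducible from the config seed.
    """
    cfg = config
    truth = (
        catalogue_or_truth.truth
        if isinstance(catalogue_or_truth, SyntheticCatalogue)
        else list(catalogue_or_truth)
    )
    rng = _rng(cfg.seed, 1)
    present = {t.species for t in truth}
    missing = [sp for sp in SPECIES if sp not in present]
    if truth and missing:
        raise ValueError(f"truth missing species: {missing}")

    counts_by_species: dict[str, CountMatrix] = {}
    metas_by_species: dict[str, list[SampleMeta]] = {}
    groups = ("naive",) + TIME_POINTS
    for sp in SPECIES:
        records = [t for t in truth if t.species == sp]
        if not records:
            continue
        tids = [t.transcript_id for t in records]
        baseline = rng.lognormal(
            cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(records)
        )
        phi = cfg.dispersion + cfg.dispersion_slope / np.maximum(baseline, 1e-8)
        rep_effect = {r: rng.normal(0.0, cfg.replicate_sd) for r in (1, 2, 3)}

        metas = [
            SampleMeta(f"{sp}_{g}_r{r}", sp, g, r)
            for g in groups
            for r in (1, 2, 3)
        ]
        lfc = np.array(
            [
                [0.0 if g == "naive" else t.planted_log2fc[g] for g in groups]
                for t in records
            ]
        )  # (T, 4)
        cols = {}
        for j, m in enumerate(metas):
            g_idx = groups.index(m.group)
            mu = baseline * np.exp(
                lfc[:, g_idx] * math.log(2.0) + rep_effect[m.replicate]
            )
            if cfg.dispersion_slope == 0.0 and cfg.dispersion <= 1e-12:
                draw = rng.poisson(mu)
            else:
                phi_pos = np.maximum(phi, 1e-12)
                n_param = 1.0 / phi_pos
                p_param = n_param / (n_param + mu)
                draw = rng.negative_binomial(n_param, p_param)
            cols[m.sample_id] = draw
        frame = pd.DataFrame(cols, index=pd.Index(tids, name="transcript_id"))
        counts_by_species[sp] = CountMatrix(frame)
        metas_by_species[sp] = metas
    return counts_by_species, metas_by_species


def generate_go_annotations(
    catalogue_or_truth, config: SimConfig
) -> tuple[list[GOAnnotation], list[str]]:
    """GO-slim table with planted enriched terms.

    The planted terms annotate the proteins of enriched-term-member
    transcripts (an excess among DE genes) plus a thin random background;
    every other term annotates proteins uniformly at the configured density.
    Returns (annotations, planted term ids).
    """
    cfg = config
    truth = (
        catalogue_or_truth.truth
        if isinstance(catalogue_or_truth, SyntheticCatalogue)
        else list(catalogue_or_truth)
    )
    rng = _rng(cfg.seed, 2)
    proteins = sorted(
        {t.homolog_protein_id for t in truth if t.homolog_protein_id is not None}
    )
    members = sorted(
        {
            t.homolog_protein_id
            for t in truth
            if t.enriched_term_member and t.homolog_protein_id is not None
        }
    )
    namespaces = ("biological_process", "molecular_function", "cellular_component")
    annotations: list[GOAnnotation] = []
    planted: list[str] = []
    for i in range(cfg.go_n_terms):
        term_id = f"GO:{i + 1:07d}"
        ns = namespaces[i % 3]
        name = f"synthetic process {i + 1}"
        if i < cfg.go_n_enriched:
            planted.append(term_id)
            annotated = set(members)
            for p in proteins:
                if p not in annotated and rng.random() < cfg.go_background_frac:
                    annotated.add(p)
        else:
            annotated = {p for p in proteins if rng.random() < cfg.go_density}
        for p in sorted(annotated):
            annotations.append(GOAnnotation(p, term_id, name, ns))
    return annotations, planted


# ---------------------------------------------------------------------------
# truth TSV and full bundle writing

_TRUTH_COLUMNS = [
    "transcript_id", "species", "true_category", "true_has_orf",
    "homolog_protein_id", "lfc_h0", "lfc_h4", "lfc_h24",
    "opposing_flag", "enriched_term_member",
]


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "species": t.species,
                "true_category": t.true_category,
                "true_has_orf": t.true_has_orf,
                "homolog_protein_id": t.homolog_protein_id or "",
                "lfc_h0": f"{t.planted_log2fc['h0']:.4f}",
                "lfc_h4": f"{t.planted_log2fc['h4']:.4f}",
                "lfc_h24": f"{t.planted_log2fc['h24']:.4f}",
                "opposing_flag": t.opposing_flag,
                "enriched_term_member": t.enriched_term_member,
            }
            for t in truth
        ],
        columns=_TRUTH_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TruthRecord(
                transcript_id=r.transcript_id,
                species=r.species,
                true_category=r.true_category,
                true_has_orf=r.true_has_orf == "True",
                homolog_protein_id=r.homolog_protein_id or None,
                planted_log2fc={
                    "h0": float(r.lfc_h0),
                    "h4": float(r.lfc_h4),
                    "h24": float(r.lfc_h24),
                },
                opposing_flag=r.opposing_flag == "True",
                enriched_term_member=r.enriched_term_member == "True",
            )
        )
    return out


def write_bundle(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle to ``outdir``.

    Emits, per species: transcripts FASTA, alignment TSV, counts TSV and
    sample metadata TSV; plus the GO map, the memory-gene panel and the truth
    table.  Same config, same seed => byte-identical files.
    """
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat = generate_catalogue(config)
    counts, metas = generate_counts(cat, config)
    go, _planted = generate_go_annotations(cat, config)

    paths: dict[str, Path] = {}
    for sp in SPECIES:
        paths[f"fasta_{sp}"] = outdir / f"transcripts_{sp}.fasta"
        _io.write_fasta(cat.transcripts[sp], paths[f"fasta_{sp}"])
        paths[f"alignments_{sp}"] = outdir / f"alignments_{sp}.tsv"
        _io.write_alignment_table(cat.alignments[sp], paths[f"alignments_{sp}"])
        paths[f"counts_{sp}"] = outdir / f"counts_{sp}.tsv"
        paths[f"meta_{sp}"] = outdir / f"samples_{sp}.tsv"
        _io.write_count_data(
            counts[sp], metas[sp], paths[f"counts_{sp}"], paths[f"meta_{sp}"]
        )
    paths["go"] = outdir / "go_map.tsv"
    _io.write_go_map(go, paths["go"])
    paths["panel"] = outdir / "panel.tsv"
    _io.write_panel(cat.panel, paths["panel"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(cat.truth, paths["truth"])
    return paths
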