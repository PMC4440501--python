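"""Cross-species comparisons via best-hit mapping to one shared proteome.

Gene identity across the two wasp species is defined by each transcript's best
alignment to the single reference proteome: transcripts of either species that
map to the same protein are treated as the same gene.  On top of that map the
module computes shared/unique transcriptome and DE-set counts, genes regulated
in opposite directions after conditioning, the known-memory-gene panel table,
antisense transcripts over panel genes, and the naive between-species
differential expression contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .de import call_de, estimate_dispersion, fit_nb_glm_lrt
from .io import AlignmentHit, CountMatrix, SampleMeta
from .classify import CategoryLabel, ANTISENSE_CATEGORIES, select_best_hit

__all__ = [
    "HomologyMap",
    "map_best_hits",
    "compare_transcriptomes",
    "find_opposing_genes",
    "known_gene_panel",
    "antisense_to_panel",
    "naive_interspecies_de",
]

logger = logging.getLogger(__name__)

TIME_POINTS = ("h0_vs_naive", "h4_vs_naive", "h24_vs_naive")


@dataclass
class HomologyMap:
    """Per species: transcript -> best-hit protein, plus the inverse index."""

    forward: dict[str, dict[str, str]]
    inverse: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.inverse:
            inv: dict[str, dict[str, set[str]]] = {}
            for sp, fwd in self.forward.items():
                for tid, pid in fwd.items():
                    inv.setdefault(pid, {}).setdefault(sp, set()).add(tid)
            self.inverse = inv

    def proteins(self, species: str) -> set[str]:
        return set(self.forward.get(species, {}).values())

    def transcripts_of(self, protein_id: str, species: str) -> set[str]:
        return set(self.inverse.get(protein_id, {}).get(species, set()))


def map_best_hits(
    hits_by_species: Mapping[str, Sequence[AlignmentHit]]
) -> HomologyMap:
    """Best proteome hit per transcript (e-value, then bitscore, then subject id)."""
    forward: dict[str, dict[str, str]] = {}
    for sp, hits in hits_by_species.items():
        per_query: dict[str, list[AlignmentHit]] = {}
        for h in hits:
            if h.subject_db == "proteome":
                per_query.setdefault(h.query_id, []).append(h)
        forward[sp] = {
            q: select_best_hit(hs).subject_id for q, hs in per_query.items()
        }
    return HomologyMap(forward=forward)


def compare_transcriptomes(
    hmap: HomologyMap,
    universe: str = "all",
    de_sets: Optional[Mapping[str, Iterable[str]]] = None,
) -> dict:
    """Shared and unique protein-level counts between the two species.

    A protein is *shared* when at least one transcript of each species maps to
    it.  With ``universe="de_sets"`` the map is first restricted to the given
    per-species DE transcript ids.
    """
    species = sorted(hmap.forward)
    if len(species) != 2:
        raise ValueError("exactly two species required")
    a, b = species
    maps = {}
    for sp in species:
        fwd = hmap.forward[sp]
        if universe == "de_sets":
            if de_sets is None:
                raise ValueError("universe='de_sets' requires de_sets")
            keep = set(de_sets.get(sp, ()))
            fwd = {t: p for t, p in fwd.items() if t in keep}
        elif universe != "all":
            raise ValueError(f"unknown universe {universe!r}")
        maps[sp] = set(fwd.values())
    shared = maps[a] & maps[b]
    return {
        "species": (a, b),
        "shared": len(shared),
        f"unique_{a}": len(maps[a] - maps[b]),
        f"unique_{b}": len(maps[b] - maps[a]),
        "shared_proteins": sorted(shared),
        f"proteins_{a}": sorted(maps[a]),
        f"proteins_{b}": sorted(maps[b]),
    }


def _sig_directions(called: pd.DataFrame) -> dict[tuple[str, str], str]:
    """(transcript_id, contrast) -> direction for significant rows."""
    sig = called[called["direction"] != "ns"]
    return {
        (r.transcript_id, r.contrast): r.direction
        for r in sig.itertuples(index=False)
    }


def find_opposing_genes(
    de_by_species: Mapping[str, pd.DataFrame],
    hmap: HomologyMap,
    same_timepoint: bool = True,
) -> pd.DataFrame:
    """Genes significantly up in one species and down in the other.

    With ``same_timepoint`` (default) the opposite calls must occur at the
    same post-conditioning time point; otherwise any pair of time points
    qualifies.  Returns one row per (protein, time-point pair) with the
    transcript-level evidence; symmetric in the two species.
    """
    species = sorted(de_by_species)
    if len(species) != 2:
        raise ValueError("exactly two species required")
    a, b = species
    dirs = {sp: _sig_directions(de_by_species[sp]) for sp in species}

    rows = []
    for pid in sorted(hmap.inverse):
        tx = {sp: hmap.transcripts_of(pid, sp) for sp in species}
        if not (tx[a] and tx[b]):
            continue
        # per species and time point: set of significant directions w/ evidence
        ev: dict[str, dict[str, dict[str, list[str]]]] = {
            sp: {tp: {} for tp in TIME_POINTS} for sp in species
        }
        for sp in species:
            for t in tx[sp]:
                for tp in TIME_POINTS:
                    d = dirs[sp].get((t, tp))
                    if d:
                        ev[sp][tp].setdefault(d, []).append(t)
        pairs = (
            [(tp, tp) for tp in TIME_POINTS]
            if same_timepoint
            else [(ta, tb) for ta in TIME_POINTS for tb in TIME_POINTS]
        )
        for tp_a, tp_b in pairs:
            for d_a, d_b in (("up", "down"), ("down", "up")):
                if d_a in ev[a][tp_a] and d_b in ev[b][tp_b]:
                    rows.append(
                        {
                            "protein_id": pid,
                            f"time_point_{a}": tp_a,
                            f"time_point_{b}": tp_b,
                            f"direction_{a}": d_a,
                            f"direction_{b}": d_b,
                            f"transcripts_{a}": ";".join(sorted(ev[a][tp_a][d_a])),
                            f"transcripts_{b}": ";".join(sorted(ev[b][tp_b][d_b])),
                        }
                    )
    cols = [
        "protein_id",
        f"time_point_{a}", f"time_point_{b}",
        f"direction_{a}", f"direction_{b}",
        f"transcripts_{a}", f"transcripts_{b}",
    ]
    return pd.DataFrame(rows, columns=cols)


def opposing_gene_ids(opposing: pd.DataFrame) -> set[str]:
    return set(opposing["protein_id"]) if len(opposing) else set()


def antisense_to_panel(
    labels_by_species: Mapping[str, Sequence[CategoryLabel]],
    panel: Sequence[tuple[str, str]],
    hmap: HomologyMap,
) -> pd.DataFrame:
    """Antisense presence and subtype over each panel gene, per species.

    An antisense transcript covers a panel gene when its deciding alignment
    subject is that gene's protein (antisense-to-protein) or a sense
    transcript mapping to that protein (antisense-to-sense); both-subtype
    transcripts count through either route.
    """
    panel_proteins = {pid for pid, _ in panel}
    rows = []
    presence: dict[tuple[str, str], set[str]] = {}
    for sp, labels in labels_by_species.items():
        fwd = hmap.forward.get(sp, {})
        for l in labels:
            if l.category not in ANTISENSE_CATEGORIES:
                continue
            targets: set[str] = set()
            for subject in l.evidence:
                if subject in panel_proteins:
                    targets.add(subject)
                pid = fwd.get(subject)  # subject may be a sense transcript
                if pid in panel_proteins:
                    targets.add(pid)
            for pid in targets:
                presence.setdefault((pid, sp), set()).add(l.category)
                rows.append(
                    {
                        "protein_id": pid,
                        "species": sp,
                        "transcript_id": l.transcript_id,
                        "subtype": l.category,
                    }
                )
    detail = pd.DataFrame(
        rows, columns=["protein_id", "species", "transcript_id", "subtype"]
    )
    species = sorted(labels_by_species)
    gene_rows = []
    for pid, symbol in panel:
        row = {"protein_id": pid, "gene_symbol": symbol}
        for sp in species:
            subtypes = presence.get((pid, sp), set())
            row[f"antisense_{sp}"] = bool(subtypes)
            row[f"subtypes_{sp}"] = ";".join(sorted(subtypes))
        gene_rows.append(row)
    summary = pd.DataFrame(gene_rows)
    summary.attrs["detail"] = detail
    if len(species) == 2:
        a, b = species
        flagged_a = summary[f"antisense_{a}"]
        flagged_b = summary[f"antisense_{b}"]
        summary.attrs["counts"] = {
            "any": int((flagged_a | flagged_b).sum()),
            f"only_{a}": int((flagged_a & ~flagged_b).sum()),
            f"only_{b}": int((~flagged_a & flagged_b).sum()),
            "both": int((flagged_a & flagged_b).sum()),
        }
    return summary


def known_gene_panel(
    panel: Sequence[tuple[str, str]],
    de_by_species: Mapping[str, pd.DataFrame],
    labels_by_species: Mapping[str, Sequence[CategoryLabel]],
    hmap: HomologyMap,
    color_threshold: float = 1.5,
) -> pd.DataFrame:
    """Panel-gene expression table: one row per gene per DE transcript rank.

    Cells hold the transcript's log2 fold change when it is significantly DE
    at that (species, time point), else ``ns``; a trailing ``*`` marks
    |log2FC| >= ``color_threshold`` (display metadata only).  When a gene has
    several DE transcripts in a species they occupy successive rows, suffixed
    (1), (2), ...  Genes absent from both species' maps get a single all-ns
    row and a warning.
    """
    species = sorted(de_by_species)
    anti = antisense_to_panel(labels_by_species, panel, hmap)
    anti_by_pid = anti.set_index("protein_id")

    lfc: dict[str, dict[tuple[str, str], float]] = {}
    sig: dict[str, set[tuple[str, str]]] = {}
    for sp in species:
        frame = de_by_species[sp]
        lfc[sp] = {
            (r.transcript_id, r.contrast): r.log2fc
            for r in frame.itertuples(index=False)
        }
        sig[sp] = {
            (r.transcript_id, r.contrast)
            for r in frame.itertuples(index=False)
            if r.direction != "ns"
        }

    rows = []
    for pid, symbol in panel:
        de_tx = {}
        for sp in species:
            tx = sorted(hmap.transcripts_of(pid, sp))
            de_tx[sp] = [
                t
                for t in tx
                if any((t, tp) in sig[sp] for tp in TIME_POINTS)
            ]
        if not any(hmap.transcripts_of(pid, sp) for sp in species):
            logger.warning("panel protein %s absent from both species maps", pid)
        n_rows = max(1, *(len(de_tx[sp]) for sp in species))
        for i in range(n_rows):
            label = symbol if n_rows == 1 else f"{symbol} ({i + 1})"
            row = {"protein_id": pid, "gene_symbol": label}
            for sp in species:
                t = de_tx[sp][i] if i < len(de_tx[sp]) else None
                row[f"transcript_{sp}"] = t or ""
                for tp in TIME_POINTS:
                    col = f"{sp}_{tp.split('_')[0]}"
                    if t is not None and (t, tp) in sig[sp]:
                        v = lfc[sp][(t, tp)]
                        mark = "*" if abs(v) >= color_threshold else ""
                        row[col] = f"{v:.2f}{mark}"
                    else:
                        row[col] = "ns"
                row[f"antisense_{sp}"] = bool(
                    anti_by_pid.loc[pid, f"antisense_{sp}"]
                )
            rows.append(row)
    cols = ["protein_id", "gene_symbol"]
    for sp in species:
        cols += [f"transcript_{sp}"] + [f"{sp}_{tp.split('_')[0]}" for tp in TIME_POINTS]
    cols += [f"antisense_{sp}" for sp in species]
    return pd.DataFrame(rows, columns=cols)


def naive_interspecies_de(
    counts_by_species: Mapping[str, CountMatrix],
    metas_by_species: Mapping[str, Sequence[SampleMeta]],
    hmap: HomologyMap,
    alpha: float = 0.05,
    bin_size: int = 50,
    shrink_weight: float = 0.7,
) -> pd.DataFrame:
    """Between-species DE of naive expression over 1:1 best-hit genes.

    The comparable set is proteins with exactly one mapped transcript in each
    species; their naive-sample counts are joined on protein id and analysed
    with the same NB GLM machinery (species factor plus replicate blocks),
    one BH family, FDR < ``alpha``.
    """
    species = sorted(counts_by_species)
    if len(species) != 2:
        raise ValueError("exactly two species required")
    a, b = species

    one_to_one = []
    for pid in sorted(hmap.inverse):
        ta = hmap.transcripts_of(pid, a)
        tb = hmap.transcripts_of(pid, b)
        if len(ta) == 1 and len(tb) == 1:
            one_to_one.append((pid, next(iter(ta)), next(iter(tb))))
    if not one_to_one:
        logger.warning("naive inter-species comparison: empty comparable set")
        return pd.DataFrame(
            columns=["transcript_id", "contrast", "log2fc", "pvalue",
                     "converged", "fdr", "direction"]
        )

    naive_metas: list[SampleMeta] = []
    blocks = []
    for sp in species:
        metas = [m for m in metas_by_species[sp] if m.group == "naive"]
        metas.sort(key=lambda m: m.replicate)
        frame = counts_by_species[sp].frame
        tx_col = {a: 1, b: 2}[sp]
        ids = [rec[tx_col] for rec in one_to_one]
        sub = frame.loc[ids, [m.sample_id for m in metas]]
        sub.index = [rec[0] for rec in one_to_one]
        blocks.append(sub)
        naive_metas.extend(metas)
    joined = pd.concat(blocks, axis=1)
    joined.index.name = "transcript_id"

    disp = estimate_dispersion(
        joined,
        [m.species for m in naive_metas],
        bin_size=bin_size,
        shrink_weight=shrink_weight,
    )
    res = fit_nb_glm_lrt(
        joined, naive_metas, disp, contrast="species_naive", factor="species"
    )
    res["contrast"] = "species_naive"
    return call_de(res, alpha=alpha)
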