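"""Transcript category classification for stranded head transcriptomes.

Each assembled transcript is assigned exactly one category by a sequential
decision procedure over its strand-aware alignments:

1. *sense* — a sense-orientation hit to the reference proteome covering more
   than 60% of the protein; transcripts whose proteome hit falls short are
   rescued by an equally good sense-orientation hit to a general protein
   database (nr).
2. Isoform propagation — every splice variant of a gene with a sense
   transcript is itself sense, regardless of its own alignment.
3. *antisense* — an antisense-orientation hit to a protein covering more than
   50% of it (``antisense_to_protein``), and/or an antisense-orientation hit
   to a sense transcript covering more than 80% of the query at >=95%
   identity, where that sense transcript itself has a proteome hit
   (``antisense_to_sense``); both conditions give ``antisense_to_both``.
4. *lncRNA* — a genome or nucleotide-database hit covering more than 80% of
   the query at >=95% identity.
5. *unknown* — everything else (misassembly or insufficient similarity).

Putative ORFs (ATG .. in-frame stop, >=30 encoded residues) are flagged for
lncRNA and unknown transcripts only; the scan is forward-strand because the
stranded library fixes transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import AlignmentHit, TranscriptRecord
from .report import percentage, round_half_up

__all__ = [
    "Thresholds",
    "CategoryLabel",
    "OrfCall",
    "CATEGORIES",
    "ANTISENSE_CATEGORIES",
    "select_best_hit",
    "classify_transcripts",
    "propagate_sense_to_isoforms",
    "find_putative_orfs",
    "summarize_categories",
    "apply_length_filter",
]

logger = logging.getLogger(__name__)

CATEGORIES = (
    "sense",
    "antisense_to_protein",
    "antisense_to_sense",
    "antisense_to_both",
    "lncRNA",
    "unknown",
)
ANTISENSE_CATEGORIES = (
    "antisense_to_protein",
    "antisense_to_sense",
    "antisense_to_both",
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs.

    Coverage bounds are strict (``>``); identity bounds are inclusive
    (``>=``).  Both boundary readings are unit-tested so the convention is
    visible.
    """

    min_transcript_len: int = 200          # bp, assembly-level filter (>=)
    sense_protein_cov: float = 0.60        # fraction of protein, strict >
    anti_protein_cov: float = 0.50         # fraction of protein, strict >
    anti_query_cov: float = 0.80           # fraction of query, strict >
    anti_identity: float = 95.0            # percent, >=
    lnc_query_cov: float = 0.80            # fraction of query, strict >
    lnc_identity: float = 95.0             # percent, >=
    orf_min_aa: int = 30                   # residues incl. Met, >=
    # whether nr-protein hits may satisfy the antisense >50% protein rule
    nr_feeds_antisense: bool = True


@dataclass(frozen=True)
class OrfCall:
    """A putative ORF in 0-based half-open transcript coordinates."""

    start: int
    end: int
    frame: int
    aa_length: int  # encoded residues incl. initiator Met, excl. stop

    def __post_init__(self):
        assert (self.end - self.start) == 3 * (self.aa_length + 1)


@dataclass(frozen=True)
class CategoryLabel:
    transcript_id: str
    category: str
    has_putative_orf: bool = False
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.has_putative_orf and self.category not in ("lncRNA", "unknown"):
            raise ValueError(
                "has_putative_orf is meaningful only for lncRNA/unknown"
            )


def apply_length_filter(
    transcripts: Sequence[TranscriptRecord], min_len: int = 200
) -> list[TranscriptRecord]:
    """Drop transcripts shorter than ``min_len`` bp (assembly-level filter)."""
    return [t for t in transcripts if t.length_bp >= min_len]


def select_best_hit(hits: Iterable[AlignmentHit]) -> Optional[AlignmentHit]:
    """Best hit: lowest e-value, then highest bitscore, then smallest subject id."""
    best = None
    for h in hits:
        if best is None:
            best = h
            continue
        key = (h.evalue, -h.bitscore, h.subject_id)
        best_key = (best.evalue, -best.bitscore, best.subject_id)
        if key < best_key:
            best = h
    return best


def _best_by_db_orientation(
    hits: Iterable[AlignmentHit],
) -> dict[str, dict[tuple[str, str], AlignmentHit]]:
    """query -> (subject_db, orientation) -> best hit."""
    grouped: dict[str, dict[tuple[str, str], list[AlignmentHit]]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, {}).setdefault(
            (h.subject_db, h.orientation), []
        ).append(h)
    return {
        q: {k: select_best_hit(v) for k, v in dbs.items()}
        for q, dbs in grouped.items()
    }


def find_putative_orfs(
    sequence: str, orf_min_aa: int = 30
) -> tuple[bool, Optional[OrfCall]]:
    """Scan the sense strand in three frames for a qualifying ORF.

    An ORF runs from an ATG to the first in-frame stop codon; it qualifies if
    it encodes at least ``orf_min_aa`` residues (initiator Met counted, stop
    excluded).  Codons containing N never match ATG or a stop.  The longest
    qualifying ORF is returned, ties broken by smaller start coordinate.
    """
    seq = sequence.upper()
    n = len(seq)
    best: Optional[OrfCall] = None
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                continue
            if codon == "ATG":
                open_starts.append(pos)
            elif codon in STOP_CODONS:
                if open_starts:
                    start = open_starts[0]  # earliest ATG gives longest ORF
                    aa = (pos - start) // 3
                    if aa >= orf_min_aa:
                        call = OrfCall(start, pos + 3, frame, aa)
                        if (
                            best is None
                            or call.aa_length > best.aa_length
                            or (
                                call.aa_length == best.aa_length
                                and call.start < best.start
                            )
                        ):
                            best = call
                open_starts = []
    return best is not None, best


def propagate_sense_to_isoforms(
    labels: Sequence[CategoryLabel], transcripts: Sequence[TranscriptRecord]
) -> list[CategoryLabel]:
    """Relabel every splice variant of a sense gene as sense.

    Idempotent: genes either have a sense isoform (all become sense) or do
    not (all unchanged).
    """
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    sense_genes = {
        gene_of[l.transcript_id]
        for l in labels
        if l.category == "sense" and l.transcript_id in gene_of
    }
    out = []
    for l in labels:
        if (
            l.category != "sense"
            and gene_of.get(l.transcript_id) in sense_genes
        ):
            out.append(
                CategoryLabel(l.transcript_id, "sense", False, l.evidence)
            )
        else:
            out.append(l)
    return out


def classify_transcripts(
    transcripts: Sequence[TranscriptRecord],
    hits: Sequence[AlignmentHit],
    thresholds: Thresholds = Thresholds(),
) -> list[CategoryLabel]:
    """Apply the sequential classification procedure to a transcript catalogue.

    ``hits`` must reference only known transcript ids.  Returns one
    :class:`CategoryLabel` per transcript, in catalogue order.
    """
    th = thresholds
    ids = {t.transcript_id for t in transcripts}
    for h in hits:
        if h.query_id not in ids:
            raise ValueError(
                f"alignment references unknown transcript id {h.query_id!r}"
            )
    best = _best_by_db_orientation(hits)
    seq_of = {t.transcript_id: t.sequence for t in transcripts}

    # proteome hits per subject-transcript id, for the antisense-to-sense rule
    has_proteome_hit = {
        q for q, dbs in best.items()
        if any(db == "proteome" for db, _ in dbs)
    }

    # --- rule 1: sense
    category: dict[str, str] = {}
    evidence: dict[str, tuple[str, ...]] = {}
    for t in transcripts:
        dbs = best.get(t.transcript_id, {})
        prot = dbs.get(("proteome", "sense"))
        if prot is not None and prot.subject_coverage > th.sense_protein_cov:
            category[t.transcript_id] = "sense"
            evidence[t.transcript_id] = (prot.subject_id,)
            continue
        nr = dbs.get(("nr_protein", "sense"))
        if nr is not None and nr.subject_coverage > th.sense_protein_cov:
            category[t.transcript_id] = "sense"
            evidence[t.transcript_id] = (nr.subject_id,)

    # --- rule 2 precursor: isoform propagation
    provisional = [
        CategoryLabel(
            t.transcript_id,
            category.get(t.transcript_id, "unknown"),
            False,
            evidence.get(t.transcript_id, ()),
        )
        for t in transcripts
    ]
    provisional = propagate_sense_to_isoforms(provisional, transcripts)
    sense_ids = {
        l.transcript_id for l in provisional if l.category == "sense"
    }

    labels: list[CategoryLabel] = []
    protein_dbs = (
        ("proteome", "nr_protein") if th.nr_feeds_antisense else ("proteome",)
    )
    for t, prov in zip(transcripts, provisional):
        tid = t.transcript_id
        if tid in sense_ids:
            labels.append(prov)
            continue
        dbs = best.get(tid, {})

        # --- rule 3: antisense
        anti_prot = None
        for db in protein_dbs:
            h = dbs.get((db, "antisense"))
            if h is not None and h.subject_coverage > th.anti_protein_cov:
                anti_prot = h if anti_prot is None else select_best_hit(
                    [anti_prot, h]
                )
        anti_sense_tx = None
        h = dbs.get(("sense_transcript", "antisense"))
        if (
            h is not None
            and h.query_coverage > th.anti_query_cov
            and h.identity_pct >= th.anti_identity
        ):
            if h.subject_id not in sense_ids:
                logger.warning(
                    "%s: antisense hit subject %s is not a sense transcript; "
                    "hit ignored",
                    tid,
                    h.subject_id,
                )
            elif h.subject_id not in has_proteome_hit:
                logger.warning(
                    "%s: antisense hit subject %s has no proteome hit; "
                    "hit ignored",
                    tid,
                    h.subject_id,
                )
            else:
                anti_sense_tx = h
        if anti_prot is not None and anti_sense_tx is not None:
            labels.append(
                CategoryLabel(
                    tid,
                    "antisense_to_both",
                    False,
                    (anti_prot.subject_id, anti_sense_tx.subject_id),
                )
            )
            continue
        if anti_prot is not None:
            labels.append(
                CategoryLabel(
                    tid, "antisense_to_protein", False, (anti_prot.subject_id,)
                )
            )
            continue
        if anti_sense_tx is not None:
            labels.append(
                CategoryLabel(
                    tid, "antisense_to_sense", False, (anti_sense_tx.subject_id,)
                )
            )
            continue

        # --- rule 4: lncRNA
        lnc_hit = None
        for db in ("genome", "nt"):
            for orient in ("sense", "antisense"):
                h = dbs.get((db, orient))
                if (
                    h is not None
                    and h.query_coverage > th.lnc_query_cov
                    and h.identity_pct >= th.lnc_identity
                ):
                    lnc_hit = h if lnc_hit is None else select_best_hit(
                        [lnc_hit, h]
                    )
        if lnc_hit is not None:
            has_orf, _ = find_putative_orfs(seq_of[tid], th.orf_min_aa)
            labels.append(
                CategoryLabel(tid, "lncRNA", has_orf, (lnc_hit.subject_id,))
            )
            continue

        # --- rule 5: unknown
        has_orf, _ = find_putative_orfs(seq_of[tid], th.orf_min_aa)
        labels.append(CategoryLabel(tid, "unknown", has_orf, ()))

    return labels


_SUMMARY_ROWS = (
    ("sense", ("sense",)),
    ("antisense", ANTISENSE_CATEGORIES),
    ("antisense_to_protein", ("antisense_to_protein",)),
    ("antisense_to_sense", ("antisense_to_sense",)),
    ("antisense_to_both", ("antisense_to_both",)),
    ("lncRNA", ("lncRNA",)),
    ("lncRNA_with_putative_orf", ("lncRNA",)),
    ("unknown", ("unknown",)),
    ("unknown_with_putative_orf", ("unknown",)),
)


def summarize_categories(
    labels: Sequence[CategoryLabel],
    transcripts: Sequence[TranscriptRecord],
    subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Category summary: count, percentage of subset total and mean length.

    Mirrors the published table layout: an aggregate antisense row with
    per-subtype subrows, and with-putative-ORF subrows for lncRNA and unknown.
    Percentages are of the subset total, rounded half-up to one decimal; mean
    lengths are integers rounded half-up.
    """
    length_of = {t.transcript_id: t.length_bp for t in transcripts}
    by_id = {l.transcript_id: l for l in labels}
    if subset is None:
        ids = [l.transcript_id for l in labels]
    else:
        ids = [i for i in subset if i in by_id]
    total = len(ids)
    rows = []
    for row_name, cats in _SUMMARY_ROWS:
        members = [i for i in ids if by_id[i].category in cats]
        if row_name.endswith("_with_putative_orf"):
            members = [i for i in members if by_id[i].has_putative_orf]
        count = len(members)
        pct = percentage(count, total) if total else 0.0
        mean_len = (
            int(round_half_up(sum(length_of[i] for i in members) / count, 0))
            if count
            else 0
        )
        rows.append(
            {
                "category": row_name,
                "count": count,
                "percent": pct,
                "mean_length_bp": mean_len,
            }
        )
    rows.append(
        {
            "category": "total",
            "count": total,
            "percent": 100.0 if total else 0.0,
            "mean_length_bp": (
                int(
                    round_half_up(
                        sum(length_of[i] for i in ids) / total, 0
                    )
                )
                if total
                else 0
            ),
        }
    )
    return pd.DataFrame(rows, columns=["category", "count", "percent", "mean_length_bp"])


def labels_to_frame(labels: Sequence[CategoryLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": l.transcript_id,
                "category": l.category,
                "has_putative_orf": l.has_putative_orf,
                "evidence_subject_id": ";".join(l.evidence),
            }
            for l in labels
        ],
        columns=[
            "transcript_id",
            "category",
            "has_putative_orf",
            "evidence_subject_id",
        ],
    )
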