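"""Readers, writers and domain containers for every file the pipeline touches.

All tabular dialects are plain TSV with a header row.  The alignment table is a
BLAST-tabular-style format extended with ``qlen``, ``slen``, ``strand`` and
``subject_db`` so that downstream classification can compute coverages and use
strand orientation.  Coordinates are 0-based half-open internally; 1-based
inclusive values appear only inside the alignment TSV, where the BLAST dialect
demands them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "AlignmentHit",
    "CountMatrix",
    "SampleMeta",
    "GOAnnotation",
    "StrandexParseError",
    "parse_trinity_id",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "read_count_data",
    "write_count_data",
    "read_go_map",
    "write_go_map",
    "read_panel",
    "write_panel",
    "go_term_sets",
    "SUBJECT_DBS",
    "SPECIES",
    "GROUPS",
    "NAMESPACES",
]


class StrandexParseError(ValueError):
    """Raised when an input file violates its dialect contract."""


SUBJECT_DBS = ("proteome", "nr_protein", "sense_transcript", "genome", "nt")
SPECIES = ("Nv", "Ng")
GROUPS = ("naive", "h0", "h4", "h24")
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

_NAMESPACE_ALIASES = {
    "bp": "biological_process",
    "mf": "molecular_function",
    "cc": "cellular_component",
    "biological_process": "biological_process",
    "molecular_function": "molecular_function",
    "cellular_component": "cellular_component",
}

_TRINITY_RE = re.compile(r"^([^_\s]+)_([^_\s]+)_seq([1-9][0-9]*)$")

_VALID_NT = frozenset("ACGTN")


def parse_trinity_id(transcript_id: str) -> tuple[str, int]:
    """Split a Trinity-style identifier into its gene id and isoform index.

    Assembled transcript names have three underscore-delimited parts, e.g.
    ``comp100_c0_seq1``; the first two parts name the "gene" and all
    transcripts sharing them are treated as splice variants of that gene.

    Returns
    -------
    (gene_id, isoform_index)
        ``("comp100_c0", 1)`` for ``comp100_c0_seq1``.
    """
    m = _TRINITY_RE.match(transcript_id)
    if m is None:
        raise StrandexParseError(
            f"malformed Trinity-style transcript id: {transcript_id!r}"
        )
    return f"{m.group(1)}_{m.group(2)}", int(m.group(3))


@dataclass(frozen=True)
class TranscriptRecord:
    """A stranded assembled transcript, 5'->3' in library sense orientation."""

    transcript_id: str
    sequence: str
    gene_id: str = field(default="")
    isoform_index: int = field(default=0)

    def __post_init__(self):
        gene_id, isoform = parse_trinity_id(self.transcript_id)
        if not self.gene_id:
            object.__setattr__(self, "gene_id", gene_id)
        elif self.gene_id != gene_id:
            raise StrandexParseError(
                f"gene_id {self.gene_id!r} does not prefix {self.transcript_id!r}"
            )
        if not self.isoform_index:
            object.__setattr__(self, "isoform_index", isoform)
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = [i for i, ch in enumerate(seq) if ch not in _VALID_NT]
        if bad:
            raise StrandexParseError(
                f"{self.transcript_id}: non-ACGTN character at position(s) "
                f"{bad[:5]}{'...' if len(bad) > 5 else ''}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One strand-aware alignment of a transcript to a database subject.

    ``orientation`` is the query strand relative to the subject's
    coding/transcript strand; ``query_coverage`` and ``subject_coverage`` are
    aligned-length fractions of query and subject length (for protein
    subjects, the fraction of the protein covered by the alignment).
    """

    query_id: str
    subject_id: str
    subject_db: str
    orientation: str  # "sense" | "antisense"
    query_coverage: float
    subject_coverage: float
    identity_pct: float
    evalue: float
    bitscore: float
    # raw dialect fields; kept when read from file so round-trips are exact
    aln_length: Optional[int] = None
    qlen: Optional[int] = None
    slen: Optional[int] = None

    def __post_init__(self):
        if self.subject_db not in SUBJECT_DBS:
            raise StrandexParseError(f"unknown subject_db {self.subject_db!r}")
        if self.orientation not in ("sense", "antisense"):
            raise StrandexParseError(f"unknown orientation {self.orientation!r}")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise StrandexParseError(
                f"{self.query_id}->{self.subject_id}: query coverage "
                f"{self.query_coverage} outside [0, 1]"
            )
        if not (0.0 <= self.subject_coverage <= 1.0):
            raise StrandexParseError(
                f"{self.query_id}->{self.subject_id}: subject coverage "
                f"{self.subject_coverage} outside [0, 1]"
            )
        if not (0.0 <= self.identity_pct <= 100.0):
            raise StrandexParseError(
                f"{self.query_id}->{self.subject_id}: identity "
                f"{self.identity_pct} outside [0, 100]"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Design annotation for one RNA-seq sample."""

    sample_id: str
    species: str
    group: str
    replicate: int

    def __post_init__(self):
        if self.species not in SPECIES:
            raise StrandexParseError(f"unknown species {self.species!r}")
        if self.group not in GROUPS:
            raise StrandexParseError(f"unknown group {self.group!r}")
        if self.replicate not in (1, 2, 3):
            raise StrandexParseError(
                f"replicate must be 1, 2 or 3, got {self.replicate}"
            )


class CountMatrix:
    """Non-negative integer counts, transcripts x samples.

    Thin wrapper over a pandas DataFrame (index = transcript ids, columns =
    sample ids) that validates integrality and non-negativity once at
    construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise StrandexParseError(f"duplicate sample ids: {dup}")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].tolist()
            raise StrandexParseError(f"duplicate transcript ids: {dup}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise StrandexParseError("counts must be integers")
            arr = arr.astype(np.int64)
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise StrandexParseError(
                f"negative count at transcript {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        self.frame = pd.DataFrame(
            arr.astype(np.int64) if arr.size else arr,
            index=counts.index,
            columns=counts.columns,
        )

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset(self, transcript_ids=None, sample_ids=None) -> "CountMatrix":
        df = self.frame
        if transcript_ids is not None:
            df = df.loc[list(transcript_ids)]
        if sample_ids is not None:
            df = df[list(sample_ids)]
        return CountMatrix(df)

    def __repr__(self):
        return (
            f"CountMatrix({len(self.frame)} transcripts x "
            f"{self.frame.shape[1]} samples)"
        )


@dataclass(frozen=True)
class GOAnnotation:
    protein_id: str
    term_id: str
    term_name: str
    namespace: str

    def __post_init__(self):
        ns = _NAMESPACE_ALIASES.get(self.namespace.lower())
        if ns is None:
            raise StrandexParseError(f"unknown GO namespace {self.namespace!r}")
        object.__setattr__(self, "namespace", ns)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[TranscriptRecord]:
    """Read stranded transcripts from FASTA; headers must be Trinity-style ids."""
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise StrandexParseError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        records.append(TranscriptRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Alignment TSV

ALIGNMENT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "slen", "strand", "subject_db",
]


def read_alignment_table(path) -> list[AlignmentHit]:
    """Read the 16-column extended BLAST-tabular TSV into AlignmentHit records.

    Coverages are computed as alignment length over query and subject length;
    the ``strand`` column (plus|minus) gives the orientation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ALIGNMENT_COLUMNS:
        raise StrandexParseError(
            f"{path}: expected columns {ALIGNMENT_COLUMNS}, got {list(df.columns)}"
        )
    hits: list[AlignmentHit] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            length = int(row.length)
            qlen = int(row.qlen)
            slen = int(row.slen)
        except ValueError as exc:
            raise StrandexParseError(f"{path}:{lineno}: {exc}") from exc
        if qlen <= 0 or slen <= 0:
            raise StrandexParseError(
                f"{path}:{lineno}: non-positive qlen/slen"
            )
        if row.strand not in ("plus", "minus"):
            raise StrandexParseError(
                f"{path}:{lineno}: strand must be plus|minus, got {row.strand!r}"
            )
        qcov = length / qlen
        scov = length / slen
        if qcov > 1.0 or scov > 1.0:
            raise StrandexParseError(
                f"{path}:{lineno}: alignment length {length} exceeds "
                f"qlen or slen"
            )
        hits.append(
            AlignmentHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                subject_db=row.subject_db,
                orientation="sense" if row.strand == "plus" else "antisense",
                query_coverage=qcov,
                subject_coverage=scov,
                identity_pct=float(row.pident),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                aln_length=length,
                qlen=qlen,
                slen=slen,
            )
        )
    return hits


def write_alignment_table(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits back to the 16-column dialect.

    Hits read from a file keep their raw length/qlen/slen and round-trip
    exactly.  For hits constructed in memory without them, the writer emits a
    canonical alignment spanning the covered prefix of query and subject;
    coverages then survive to ~1e-6 and every other field exactly.
    """
    rows = []
    for h in hits:
        if h.aln_length is not None and h.qlen and h.slen:
            length, qlen, slen = h.aln_length, h.qlen, h.slen
        else:
            scale = 10**6
            length = int(round(h.query_coverage * scale))
            qlen = scale
            slen = (
                int(round(length / h.subject_coverage))
                if h.subject_coverage > 0
                else scale
            )
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": f"{h.identity_pct:.3f}",
                "length": length,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 1,
                "qend": max(length, 1),
                "sstart": 1,
                "send": max(length, 1),
                "evalue": f"{h.evalue:.3g}",
                "bitscore": f"{h.bitscore:.1f}",
                "qlen": qlen,
                "slen": slen,
                "strand": "plus" if h.orientation == "sense" else "minus",
                "subject_db": h.subject_db,
            }
        )
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts + sample metadata


def read_count_data(counts_path, meta_path) -> tuple[CountMatrix, list[SampleMeta]]:
    """Read a counts TSV (transcript_id + one column per sample) and its design.

    Every sample column must appear in the metadata; a full design has all
    (group, replicate) cells, and missing cells only warn because partial
    designs are still analysable for some contrasts.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts_df.index.name != "transcript_id":
        raise StrandexParseError(
            f"{counts_path}: first column must be 'transcript_id'"
        )
    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    expected = ["sample_id", "species", "group", "replicate"]
    if list(meta_df.columns) != expected:
        raise StrandexParseError(
            f"{meta_path}: expected columns {expected}, got {list(meta_df.columns)}"
        )
    metas = [
        SampleMeta(
            sample_id=r.sample_id,
            species=r.species,
            group=r.group,
            replicate=int(r.replicate),
        )
        for r in meta_df.itertuples(index=False)
    ]
    combos = {(m.species, m.group, m.replicate) for m in metas}
    if len(combos) != len(metas):
        raise StrandexParseError(
            f"{meta_path}: duplicate (species, group, replicate) combinations"
        )
    meta_ids = {m.sample_id for m in metas}
    missing = [s for s in counts_df.columns if s not in meta_ids]
    if missing:
        raise StrandexParseError(
            f"sample(s) in counts absent from metadata: {missing}"
        )
    try:
        matrix = CountMatrix(counts_df)
    except StrandexParseError as exc:
        raise StrandexParseError(f"{counts_path}: {exc}") from exc
    metas = [m for m in metas if m.sample_id in set(counts_df.columns)]
    _warn_incomplete_design(metas)
    return matrix, metas


def _warn_incomplete_design(metas: Sequence[SampleMeta]) -> None:
    import warnings

    by_species: dict[str, set[tuple[str, int]]] = {}
    for m in metas:
        by_species.setdefault(m.species, set()).add((m.group, m.replicate))
    for sp, cells in by_species.items():
        absent = [
            (g, r) for g in GROUPS for r in (1, 2, 3) if (g, r) not in cells
        ]
        if absent:
            warnings.warn(
                f"{sp}: design missing (group, replicate) cells: {absent}",
                stacklevel=3,
            )


def write_count_data(matrix: CountMatrix, metas: Sequence[SampleMeta],
                     counts_path, meta_path) -> None:
    df = matrix.frame.copy()
    df.index.name = "transcript_id"
    df.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "species": m.species,
                "group": m.group,
                "replicate": m.replicate,
            }
            for m in metas
        ]
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO map and gene panel


def read_go_map(path) -> list[GOAnnotation]:
    """Read the protein->GO-slim table; duplicate (protein, term) rows collapse."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    expected = ["protein_id", "term_id", "term_name", "namespace"]
    if list(df.columns) != expected:
        raise StrandexParseError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    out: dict[tuple[str, str], GOAnnotation] = {}
    for r in df.itertuples(index=False):
        ann = GOAnnotation(r.protein_id, r.term_id, r.term_name, r.namespace)
        out[(ann.protein_id, ann.term_id)] = ann
    return list(out.values())


def write_go_map(annotations: Iterable[GOAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "term_id": a.term_id,
                "term_name": a.term_name,
                "namespace": a.namespace,
            }
            for a in annotations
        ],
        columns=["protein_id", "term_id", "term_name", "namespace"],
    ).to_csv(path, sep="\t", index=False)


def go_term_sets(annotations: Iterable[GOAnnotation]) -> dict[str, set[str]]:
    """protein_id -> set of annotated term ids."""
    sets: dict[str, set[str]] = {}
    for a in annotations:
        sets.setdefault(a.protein_id, set()).add(a.term_id)
    return sets


def read_panel(path) -> list[tuple[str, str]]:
    """Read the known-memory-gene panel: (protein_id, gene_symbol) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["protein_id", "gene_symbol"]
    if list(df.columns) != expected:
        raise StrandexParseError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    return [(r.protein_id, r.gene_symbol) for r in df.itertuples(index=False)]


def write_panel(panel: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(panel, columns=["protein_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def round_counts(values: np.ndarray) -> np.ndarray:
    """Round real-valued effective counts to integers, half to even."""
    return np.rint(np.asarray(values, dtype=float)).astype(np.int64)
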