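"""Pre-reconstruction CDS preparation.

Covers the data-cleaning chain applied to helper-NLR coding sequences before
any phylogenetic inference: frame/stop sanity filtering, translation, codon
threading of a protein alignment back onto nucleotides, gappy-column
trimming, and exact-duplicate removal.

Filter order is fixed: (1) drop CDS whose length is not a multiple of three,
(2) drop CDS with an internal stop codon, (3) strip one terminal stop codon,
(4) apply the length window to the stop-stripped length (inclusive bounds).
Running the filter on its own output is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .io_formats import DNA, GAP, PROTEIN, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

REASON_INTERNAL_STOP = "internal_stop"
REASON_NOT_MULTIPLE_OF_THREE = "not_multiple_of_three"
REASON_LENGTH = "length_out_of_range"


@dataclass
class FilterReport:
    """Audit trail of :func:`filter_cds`: every input id is accounted for."""

    kept: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    trimmed_terminal_stop: list[str] = field(default_factory=list)


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def has_internal_stop(seq: str) -> bool:
    """True if any codon before the last is a stop codon (frame assumed)."""
    return any(c in STOP_CODONS for c in _codons(seq)[:-1])


def filter_cds(
    records: Sequence[SequenceRecord],
    min_len: int = 2400,
    max_len: int = 2800,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Sanity-filter coding sequences.

    Parameters
    ----------
    records : DNA records (unaligned CDS).
    min_len, max_len : inclusive length window applied after terminal-stop
        stripping, in nucleotides.  Defaults are the helper-NLR window
        (full-length NRCs run roughly 2.4–2.8 kb).

    Returns the kept records (terminal stop removed where present) and a
    :class:`FilterReport`.  Problems never raise; they become rejections.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept: list[SequenceRecord] = []
    report = FilterReport()
    for rec in records:
        seq = rec.seq
        if len(seq) % 3 != 0:
            report.rejected.append((rec.id, REASON_NOT_MULTIPLE_OF_THREE))
            continue
        if has_internal_stop(seq):
            report.rejected.append((rec.id, REASON_INTERNAL_STOP))
            continue
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
            report.trimmed_terminal_stop.append(rec.id)
        if not seq or not (min_len <= len(seq) <= max_len):
            report.rejected.append((rec.id, REASON_LENGTH))
            continue
        kept.append(SequenceRecord(id=rec.id, seq=seq, alphabet=DNA))
        report.kept.append(rec.id)
    return kept, report


def translate_cds(record: SequenceRecord) -> SequenceRecord:
    """Translate a frame-clean CDS with the standard genetic code.

    Codons containing N translate to X.  An internal stop raises — it means
    :func:`filter_cds` was skipped upstream.
    """
    if len(record.seq) % 3 != 0:
        raise ValueError(f"{record.id}: CDS length {len(record.seq)} is not a multiple of 3")
    if has_internal_stop(record.seq):
        raise ValueError(f"{record.id}: internal stop codon; run filter_cds first")
    aa = str(Seq(record.seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return SequenceRecord(id=record.id, seq=aa, alphabet=PROTEIN)


@dataclass
class CodonAlignment:
    """A nucleotide alignment whose gaps respect codon boundaries.

    ``column_map`` tracks, for each retained nucleotide column, its 0-based
    index in the original (untrimmed) alignment.
    """

    alignment: Alignment
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        aln = self.alignment
        if aln.n_columns % 3 != 0:
            raise ValueError("codon alignment length must be divisible by 3")
        if not self.column_map:
            self.column_map = list(range(aln.n_columns))
        if len(self.column_map) != aln.n_columns:
            raise ValueError("column_map length must equal alignment width")
        for rec in aln.records:
            for k in range(0, len(rec.seq), 3):
                codon = rec.seq[k : k + 3]
                if GAP in codon and codon != GAP * 3:
                    raise ValueError(
                        f"{rec.id}: gap does not cover a whole codon at column {k + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return self.alignment.n_columns // 3

    @property
    def ids(self) -> list[str]:
        return self.alignment.ids

    def codon_row(self, seq_id: str) -> list[str]:
        seq = self.alignment[seq_id].seq
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass(frozen=True)
class SequencePatch:
    """A manual single-residue edit applied to a protein alignment row.

    ``position`` is the 1-based residue index counted over non-gap characters
    of the row; ``replacement`` the new residue.
    """

    seq_id: str
    position: int
    replacement: str


def apply_patches(aln: Alignment, patches: Iterable[SequencePatch]) -> Alignment:
    """Apply manual residue edits to a protein alignment (before threading)."""
    rows = {r.id: list(r.seq) for r in aln.records}
    for p in patches:
        if p.seq_id not in rows:
            raise KeyError(f"patch target {p.seq_id!r} not in alignment")
        row = rows[p.seq_id]
        count = 0
        for j, c in enumerate(row):
            if c != GAP:
                count += 1
                if count == p.position:
                    logger.info("patch %s position %d: %s -> %s", p.seq_id, p.position, c, p.replacement)
                    row[j] = p.replacement.upper()
                    break
        else:
            raise IndexError(f"patch position {p.position} beyond {p.seq_id!r}")
    records = [
        SequenceRecord(id=r.id, seq="".join(rows[r.id]), alphabet=aln.alphabet)
        for r in aln.records
    ]
    return Alignment(records=records, alphabet=aln.alphabet)


def thread_codons(protein_aln: Alignment, cds: Sequence[SequenceRecord]) -> CodonAlignment:
    """Thread each CDS onto its aligned protein row (back-translation).

    Each aligned residue is replaced by its source codon and each protein gap
    by ``---``, so degapping any output row reproduces the input CDS exactly.
    A residue that disagrees with the codon's translation raises, naming the
    first mismatching residue index.
    """
    by_id = {r.id: r for r in cds}
    out: list[SequenceRecord] = []
    for prot in protein_aln.records:
        if prot.id not in by_id:
            raise KeyError(f"no CDS provided for aligned sequence {prot.id!r}")
        nuc = by_id[prot.id].seq
        codons = _codons(nuc)
        aa = str(Seq(nuc).translate())
        threaded: list[str] = []
        k = 0  # residue cursor
        for c in prot.seq:
            if c == GAP:
                threaded.append(GAP * 3)
                continue
            if k >= len(codons):
                raise ValueError(f"{prot.id}: protein row longer than CDS translation")
            expected = aa[k]
            if c != expected and not (c == "X" and "N" in codons[k]):
                raise ValueError(
                    f"{prot.id}: residue {k + 1} is {c!r} in the protein alignment "
                    f"but codon {codons[k]} translates to {expected!r}"
                )
            threaded.append(codons[k])
            k += 1
        if k != len(codons):
            raise ValueError(
                f"{prot.id}: CDS has {len(codons)} codons but protein row uses {k}"
            )
        out.append(SequenceRecord(id=prot.id, seq="".join(threaded), alphabet=DNA))
    return CodonAlignment(alignment=Alignment(records=out, alphabet=DNA))


def trim_gappy_columns(
    aln: Alignment | CodonAlignment, g: float = 0.9
) -> tuple[Alignment | CodonAlignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``g``.

    For a plain alignment the unit is the single column; for a
    :class:`CodonAlignment` the unit is the codon triple, removed iff the
    pooled gap fraction over its three columns exceeds ``g`` (preserving
    reading frame).  Returns the trimmed object and the retained original
    column indices (0-based).
    """
    if not 0 <= g <= 1:
        raise ValueError("g must be in [0, 1]")
    if isinstance(aln, CodonAlignment):
        inner = aln.alignment
        n = inner.n_rows
        keep_cols: list[int] = []
        for k in range(0, inner.n_columns, 3):
            gaps = sum(
                1
                for r in inner.records
                for j in (k, k + 1, k + 2)
                if r.seq[j] == GAP
            )
            if gaps / (3 * n) <= g:
                keep_cols.extend((k, k + 1, k + 2))
        if not keep_cols:
            raise ValueError(f"gappy trimming at g={g} removed every codon column")
        records = [
            SequenceRecord(
                id=r.id, seq="".join(r.seq[j] for j in keep_cols), alphabet=inner.alphabet
            )
            for r in inner.records
        ]
        col_map = [aln.column_map[j] for j in keep_cols]
        trimmed = CodonAlignment(
            alignment=Alignment(records=records, alphabet=inner.alphabet),
            column_map=col_map,
        )
        return trimmed, col_map
    n = aln.n_rows
    keep = [
        j
        for j in range(aln.n_columns)
        if aln.column(j).count(GAP) / n <= g
    ]
    if not keep:
        raise ValueError(f"gappy trimming at g={g} removed every column")
    records = [
        SequenceRecord(id=r.id, seq="".join(r.seq[j] for j in keep), alphabet=aln.alphabet)
        for r in aln.records
    ]
    return Alignment(records=records, alphabet=aln.alphabet), keep


def deduplicate(
    records: Sequence[SequenceRecord] | Alignment,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Collapse exact full-length duplicates (case-normalised string equality).

    The first occurrence in input order is the retained representative.
    Returns the non-redundant records and a map representative id -> member
    ids (including the representative itself).
    """
    if isinstance(records, Alignment):
        records = records.records
    reps: list[SequenceRecord] = []
    clusters: dict[str, list[str]] = {}
    by_seq: dict[str, str] = {}
    for r in records:
        if r.seq in by_seq:
            clusters[by_seq[r.seq]].append(r.id)
        else:
            by_seq[r.seq] = r.id
            reps.append(r)
            clusters[r.id] = [r.id]
    return reps, clusters
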