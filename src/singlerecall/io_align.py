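"""Reference, alignment and barcode-table input.

Converts CIGAR-aligned nanopore reads into reference-coordinate event
streams (one event per reference position touched by the read: a base
call with its Phred quality, or a deletion), applies the read filters
used for amplicon libraries, and groups reads by variant barcode.

Coordinates are 0-based half-open internally; every user-facing report
(mutation labels, scored tables) is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ._util import (
    BASES,
    DEL,
    FORWARD,
    REVERSE,
    STRAND_NAMES,
    SYMBOLS,
    encode_bases,
    mean_qscore,
    sequence_checksum,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReferenceSequence:
    """The known wild-type amplicon; the coordinate frame for everything."""

    name: str
    bases: str

    def __post_init__(self):
        if len(self.bases) < 1:
            raise ValueError("reference must contain at least one base")
        object.__setattr__(self, "_codes", encode_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        """uint8 codes (A=0, C=1, G=2, T=3) of the reference bases."""
        return self._codes

    @property
    def checksum(self) -> str:
        return sequence_checksum(self.bases)

    def base_counts(self) -> np.ndarray:
        """counts_reference(n): per-base tallies over the reference."""
        return np.bincount(self.codes, minlength=4)

    def homopolymer_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of identical bases of length >= 2, half-open."""
        runs = []
        start = 0
        codes = self.codes
        for i in range(1, len(codes) + 1):
            if i == len(codes) or codes[i] != codes[start]:
                if i - start >= 2:
                    runs.append((start, i))
                start = i
        return runs


class AlignedEvent(NamedTuple):
    read_id: str
    ref_pos: int
    observed: str  # one of A, C, G, T, '-'
    qscore: int  # -1 while a deletion is still unscored
    strand: str  # '+' or '-'


@dataclass
class Insertion:
    """Bases inserted before ``ref_gap_position`` (reference coordinate)."""

    ref_gap_position: int
    bases: str
    qscores: np.ndarray


@dataclass
class ReadRecord:
    """One primary alignment as a reference-coordinate event stream.

    ``positions``/``symbols``/``qscores`` are parallel arrays; a symbol
    code of 4 marks a deletion relative to the reference, whose qscore
    stays -1 until the neighbour-minimum rule assigns one. Insertions are
    retained for bookkeeping but never enter model coordinates.
    """

    read_id: str
    strand: int  # FORWARD or REVERSE
    positions: np.ndarray  # int32, strictly increasing
    symbols: np.ndarray  # uint8 codes into SYMBOLS
    qscores: np.ndarray  # int16, -1 = unset (deletions before scoring)
    insertions: list[Insertion] = field(default_factory=list)
    barcode: str | None = None

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"read {self.read_id}: ref positions not strictly increasing")

    @property
    def length_nt(self) -> int:
        """Number of base calls: non-deletion events plus inserted bases."""
        n_ins = sum(len(ins.bases) for ins in self.insertions)
        return int(np.sum(self.symbols != DEL)) + n_ins

    @property
    def mean_q(self) -> float:
        qs = [self.qscores[self.symbols != DEL]]
        qs.extend(ins.qscores for ins in self.insertions)
        return mean_qscore(np.concatenate(qs) if qs else np.empty(0))

    @property
    def strand_name(self) -> str:
        return STRAND_NAMES[self.strand]

    def events(self) -> Iterator[AlignedEvent]:
        for p, s, q in zip(self.positions, self.symbols, self.qscores):
            yield AlignedEvent(self.read_id, int(p), SYMBOLS[s], int(q), self.strand_name)

    def copy(self) -> "ReadRecord":
        return replace(
            self,
            positions=self.positions.copy(),
            symbols=self.symbols.copy(),
            qscores=self.qscores.copy(),
            insertions=list(self.insertions),
        )


def load_reference(fasta_path: str | Path) -> ReferenceSequence:
    """Load the (single) reference from a FASTA file.

    The first record is used; additional records are rejected with a
    warning since the method is single-reference. Lower-case bases are
    normalised; ambiguity codes raise with the offending position.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s) as the reference",
            fasta_path, len(records), records[0].id,
        )
    rec = records[0]
    bases = str(rec.seq).upper()
    try:
        return ReferenceSequence(name=rec.id, bases=bases)
    except ValueError as exc:
        raise ValueError(f"reference {rec.id}: {exc}") from None


# CIGAR operation codes (pysam numeric convention)
_CONSUME_BOTH = {0, 7, 8}  # M, =, X
_OP_INS, _OP_DEL, _OP_REFSKIP, _OP_SOFT, _OP_HARD, _OP_PAD = 1, 2, 3, 4, 5, 6


def parse_alignments(
    sam_or_bam_path: str | Path,
    reference: ReferenceSequence,
) -> Iterator[ReadRecord]:
    """Stream primary alignments as :class:`ReadRecord` event streams.

    CIGAR M/=/X become base events at their reference positions, D one
    deletion event per deleted reference base (qscore unset), I an
    insertion entry, S/H are dropped. Unmapped, secondary and
    supplementary records are skipped so each amplicon read contributes
    a single event stream.
    """
    path = str(sam_or_bam_path)
    save = pysam.set_verbosity(0)
    afile = pysam.AlignmentFile(path, check_sq=False)
    pysam.set_verbosity(save)
    with afile:
        for aln in afile:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != reference.name:
                raise ValueError(
                    f"read {aln.query_name} aligned to {aln.reference_name!r}, "
                    f"expected reference {reference.name!r}"
                )
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None or quals is None:
                raise ValueError(f"read {aln.query_name} carries no base qualities")
            yield _walk_cigar(aln, reference)


def _walk_cigar(aln: pysam.AlignedSegment, reference: ReferenceSequence) -> ReadRecord:
    seq = aln.query_sequence
    quals = np.asarray(aln.query_qualities, dtype=np.int16)
    positions: list[int] = []
    symbols: list[int] = []
    qscores: list[int] = []
    insertions: list[Insertion] = []
    rpos = aln.reference_start
    qpos = 0
    L = len(reference)
    for op, length in aln.cigartuples:
        if op in _CONSUME_BOTH:
            for k in range(length):
                if rpos + k >= L:
                    raise ValueError(
                        f"read {aln.query_name}: alignment overruns reference length {L}"
                    )
                base = seq[qpos + k].upper()
                code = SYMBOLS.find(base)
                if code < 0 or code == DEL:
                    raise ValueError(
                        f"read {aln.query_name}: non-ACGT base {base!r} in aligned segment"
                    )
                positions.append(rpos + k)
                symbols.append(code)
                qscores.append(int(quals[qpos + k]))
            rpos += length
            qpos += length
        elif op == _OP_DEL or op == _OP_REFSKIP:
            for k in range(length):
                positions.append(rpos + k)
                symbols.append(DEL)
                qscores.append(-1)
            rpos += length
        elif op == _OP_INS:
            insertions.append(
                Insertion(rpos, seq[qpos:qpos + length].upper(), quals[qpos:qpos + length].copy())
            )
            qpos += length
        elif op == _OP_SOFT:
            qpos += length
        elif op == _OP_HARD or op == _OP_PAD:
            continue
        else:
            raise ValueError(f"read {aln.query_name}: unsupported CIGAR op {op}")
    if qpos != len(seq):
        raise ValueError(
            f"read {aln.query_name}: CIGAR consumes {qpos} query bases, sequence has {len(seq)}"
        )
    return ReadRecord(
        read_id=aln.query_name,
        strand=REVERSE if aln.is_reverse else FORWARD,
        positions=np.asarray(positions, dtype=np.int32),
        symbols=np.asarray(symbols, dtype=np.uint8),
        qscores=np.asarray(qscores, dtype=np.int16),
        insertions=insertions,
    )


def filter_reads(
    records: Iterable[ReadRecord],
    min_len: int = 1700,
    max_len: int = 2100,
    min_mean_q: float = 10.0,
) -> Iterator[ReadRecord]:
    """Keep reads with min_len <= length <= max_len and mean Q strictly above the cutoff.

    Defaults follow the standard amplicon preprocessing (full-length
    KlenTaq amplicons, mean Qscore larger than 10). Drop counts per
    criterion are logged.
    """
    if min_len < 0 or max_len < 0 or min_mean_q < 0:
        raise ValueError("filter thresholds must be non-negative")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    dropped_short = dropped_long = dropped_quality = kept = 0
    for rec in records:
        n = rec.length_nt
        if n < min_len:
            dropped_short += 1
            continue
        if n > max_len:
            dropped_long += 1
            continue
        if not rec.mean_q > min_mean_q:
            dropped_quality += 1
            continue
        kept += 1
        yield rec
    logger.info(
        "filter_reads: kept %d; dropped %d (short), %d (long), %d (mean Q <= %.3g)",
        kept, dropped_short, dropped_long, dropped_quality, min_mean_q,
    )


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping read_id -> barcode (exact-match semantics)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    if "read_id" in cols and "barcode" in cols:
        df.columns = cols
        pairs = df[["read_id", "barcode"]].itertuples(index=False)
    else:  # headerless two-column table
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        pairs = df.iloc[:, :2].itertuples(index=False)
    table: dict[str, str] = {}
    for read_id, barcode in pairs:
        if read_id in table and table[read_id] != barcode:
            raise ValueError(
                f"read {read_id} listed under conflicting barcodes "
                f"{table[read_id]!r} and {barcode!r}"
            )
        table[read_id] = barcode
    return table


def group_by_barcode(
    records: Iterable[ReadRecord],
    barcode_table: Mapping[str, str] | str | Path,
) -> dict[str, list[ReadRecord]]:
    """Group reads by exact barcode match; unknown reads go to "unassigned"."""
    if not isinstance(barcode_table, Mapping):
        barcode_table = read_barcode_table(barcode_table)
    groups: dict[str, list[ReadRecord]] = {}
    for rec in records:
        barcode = barcode_table.get(rec.read_id, UNASSIGNED)
        rec.barcode = None if barcode == UNASSIGNED else barcode
        groups.setdefault(barcode, []).append(rec)
    for barcode, members in sorted(groups.items()):
        logger.info("barcode %s: %d reads", barcode, len(members))
    return groups


def write_sam(
    records: Iterable[ReadRecord],
    reference: ReferenceSequence,
    path: str | Path,
) -> None:
    """Write event streams back to a (plain-text) SAM file.

    The inverse of :func:`parse_alignments` for records produced by this
    package: base events become M runs, deletions D runs, insertions I
    runs; the SEQ field is stored reference-oriented with flag 16 marking
    reverse-strand reads.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": reference.name, "LN": len(reference)}],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(_to_aligned_segment(rec, header))


def _to_aligned_segment(rec: ReadRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    ins_at: dict[int, Insertion] = {i.ref_gap_position: i for i in rec.insertions}
    cigar: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    qual_parts: list[np.ndarray] = []

    def emit(op: int, length: int):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    start = int(rec.positions[0])
    prev = start - 1
    for p, s, q in zip(rec.positions, rec.symbols, rec.qscores):
        p = int(p)
        if p != prev + 1:
            raise ValueError(f"read {rec.read_id}: gap in event stream at {p}")
        if p in ins_at:
            ins = ins_at[p]
            emit(_OP_INS, len(ins.bases))
            seq_parts.append(ins.bases)
            qual_parts.append(np.asarray(ins.qscores, dtype=np.int16))
        if s == DEL:
            emit(_OP_DEL, 1)
        else:
            emit(0, 1)
            seq_parts.append(SYMBOLS[s])
            qual_parts.append(np.asarray([q], dtype=np.int16))
        prev = p
    end_gap = prev + 1
    if end_gap in ins_at:  # insertion after the last aligned base
        ins = ins_at[end_gap]
        emit(_OP_INS, len(ins.bases))
        seq_parts.append(ins.bases)
        qual_parts.append(np.asarray(ins.qscores, dtype=np.int16))

    a = pysam.AlignedSegment(header)
    a.query_name = rec.read_id
    a.reference_id = 0
    a.reference_start = start
    a.flag = 16 if rec.strand == REVERSE else 0
    a.mapping_quality = 60
    a.cigartuples = cigar
    a.query_sequence = "".join(seq_parts)
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(int(q) + 33) for q in np.concatenate(qual_parts))
    )
    return a
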