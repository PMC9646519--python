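"""Per-event probability of being correct for variant reads.

Reference-matching calls keep the basecaller's own confidence,
p_Guppy = 1 - 10^(-Q/10). Mismatches and deletions are re-scored by
evaluating the trained logistic cell for their (position, symbol,
strand) at the reported Qscore. Deletions first receive a proxy Qscore:
the minimum quality of their nearest non-deletion neighbours in the
read, exploiting the correlation of quality between consecutive calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import DEL, STRAND_NAMES, SYMBOLS, clamp_prob, phred_to_perror, xopen
from .error_model import FitModel
from .io_align import ReadRecord, ReferenceSequence

SOURCE_GUPPY = 0
SOURCE_SINGLE = 1
SOURCE_DELETION = 2  # deletion rule (neighbour-min Q) + model cell
_SOURCE_NAMES = ("guppy", "single", "deletion_rule+single")


class ScoredEvent(NamedTuple):
    read_id: str
    ref_pos: int
    observed: str
    qscore: int
    strand: str
    p_right: float
    source: str


@dataclass
class ScoredRead:
    """A read with a probability of being correct attached to every event."""

    read_id: str
    strand: int
    positions: np.ndarray
    symbols: np.ndarray
    qscores: np.ndarray
    p_right: np.ndarray
    source: np.ndarray  # uint8 codes into _SOURCE_NAMES
    barcode: str | None = None
    insertions: list = field(default_factory=list)

    def events(self) -> Iterator[ScoredEvent]:
        name = STRAND_NAMES[self.strand]
        for p, s, q, pr, src in zip(
            self.positions, self.symbols, self.qscores, self.p_right, self.source
        ):
            yield ScoredEvent(
                self.read_id, int(p), SYMBOLS[s], int(q), name,
                float(pr), _SOURCE_NAMES[src],
            )


def p_guppy(qscore):
    """Basecaller confidence: p = 1 - 10^(-Q/10)."""
    q = np.asarray(qscore, dtype=float)
    if np.any(q < 0):
        raise ValueError("Qscore must be non-negative")
    out = 1.0 - phred_to_perror(q)
    return float(out) if np.isscalar(qscore) else out


def assign_deletion_qscores(record: ReadRecord) -> ReadRecord:
    """Give each deletion the minimum Qscore of its flanking base calls.

    Neighbours are taken in read-event order; a run of consecutive
    deletions shares the min of the two flanking calls, and a run at a
    read end takes its single existing neighbour's quality.
    """
    symbols = record.symbols
    is_del = symbols == DEL
    if not np.any(is_del):
        return record
    if np.all(is_del):
        raise ValueError(f"read {record.read_id} consists only of deletion events")
    out = record.copy()
    qs = out.qscores
    n = len(symbols)
    i = 0
    while i < n:
        if not is_del[i]:
            i += 1
            continue
        j = i
        while j < n and is_del[j]:
            j += 1
        flanks = []
        if i > 0:
            flanks.append(int(qs[i - 1]))
        if j < n:
            flanks.append(int(qs[j]))
        qs[i:j] = min(flanks)
        i = j
    return out


def score_read(
    record: ReadRecord,
    model: FitModel,
    reference: ReferenceSequence,
) -> ScoredRead:
    """Attach p_right to every aligned event of one read.

    Matches get p_Guppy(Q); substitutions and deletions are evaluated in
    the model cell for their position/symbol/strand. Insertions pass
    through unscored with their original basecaller qualities.
    """
    if model.reference_checksum != reference.checksum:
        raise ValueError(
            "model was trained on a different reference "
            f"(checksum {model.reference_checksum} != {reference.checksum})"
        )
    rec = record
    if np.any((rec.symbols == DEL) & (rec.qscores < 0)):
        rec = assign_deletion_qscores(rec)
    ref_at = reference.codes[rec.positions]
    is_match = rec.symbols == ref_at
    is_del = rec.symbols == DEL
    p = np.empty(len(rec.positions), dtype=float)
    q = rec.qscores.astype(float)
    p[is_match] = p_guppy(q[is_match])
    mism = ~is_match
    if np.any(mism):
        p[mism] = model.predict(
            rec.positions[mism], rec.strand, rec.symbols[mism], q[mism]
        )
    source = np.where(is_match, SOURCE_GUPPY, SOURCE_SINGLE).astype(np.uint8)
    source[is_del] = SOURCE_DELETION
    return ScoredRead(
        read_id=rec.read_id,
        strand=rec.strand,
        positions=rec.positions.copy(),
        symbols=rec.symbols.copy(),
        qscores=rec.qscores.copy(),
        p_right=p,
        source=source,
        barcode=rec.barcode,
        insertions=list(rec.insertions),
    )


def score_reads(
    records: Iterable[ReadRecord],
    model: FitModel,
    reference: ReferenceSequence,
) -> Iterator[ScoredRead]:
    for rec in records:
        yield score_read(rec, model, reference)


def write_scored_table(scored: Iterable[ScoredRead], path: str | Path) -> None:
    """Write scored events as TSV (1-based positions), gzip by suffix."""
    with xopen(path, "wt") as fh:
        fh.write("read_id\tposition\tstrand\tobserved\tqscore\tp_right\tsource\n")
        for read in scored:
            for ev in read.events():
                fh.write(
                    f"{ev.read_id}\t{ev.ref_pos + 1}\t{ev.strand}\t{ev.observed}\t"
                    f"{ev.qscore}\t{ev.p_right:.6g}\t{ev.source}\n"
                )


def read_scored_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
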