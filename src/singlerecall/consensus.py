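"""Weighted per-position consensus of a group of reads.

Three weighting schemes are supported: plain majority vote ("none"),
basecaller confidence p_Guppy ("guppy"), and the recalibrated p_right
("single"). For the recalibrated method, deletions inside homopolymer
runs — whose placement within the run is an arbitrary choice of the
aligner — are first normalised to the 3' end of the run on the forward
reference strand, so that identical deletions vote for the same
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import BASES, DEL, SYMBOLS
from .io_align import ReadRecord, ReferenceSequence
from .rescoring import ScoredRead, p_guppy

METHODS = ("single", "guppy", "none")


@dataclass
class ConsensusResult:
    group_id: str | None
    method: str
    winners: np.ndarray  # (L,) uint8 symbol codes
    weights: np.ndarray  # (L, 5) per-symbol weight totals
    coverage: np.ndarray  # (L,) reads covering each position
    no_coverage: np.ndarray  # (L,) bool: position took the reference by default
    sequence: str = ""
    diffs: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return int(self.coverage.max()) if self.coverage.size else 0


def sort_homopolymer_deletions(
    reads: Sequence[ReadRecord | ScoredRead],
    reference: ReferenceSequence,
) -> list[ReadRecord | ScoredRead]:
    """Normalise deletion placement inside homopolymer runs.

    Within each maximal run of >= 2 identical reference bases, each
    read's deletion events are moved to the highest reference positions
    of the run (the 3' side on the forward strand) and its base calls
    are packed to the 5' side, keeping their order. Qscores and any
    attached probabilities travel with their events, so per-run symbol
    multisets and total weights are conserved.
    """
    runs = reference.homopolymer_runs()
    out = []
    for read in reads:
        new = read.copy() if isinstance(read, ReadRecord) else _copy_scored(read)
        pos = new.positions
        for start, end in runs:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            if hi - lo < 2:
                continue
            sl = slice(lo, hi)
            syms = new.symbols[sl]
            is_del = syms == DEL
            if not is_del.any() or is_del.all():
                continue
            order = np.concatenate([np.flatnonzero(~is_del), np.flatnonzero(is_del)])
            new.symbols[sl] = syms[order]
            new.qscores[sl] = new.qscores[sl][order]
            if hasattr(new, "p_right"):
                new.p_right[sl] = new.p_right[sl][order]
                new.source[sl] = new.source[sl][order]
        out.append(new)
    return out


def _copy_scored(read: ScoredRead) -> ScoredRead:
    return ScoredRead(
        read_id=read.read_id,
        strand=read.strand,
        positions=read.positions.copy(),
        symbols=read.symbols.copy(),
        qscores=read.qscores.copy(),
        p_right=read.p_right.copy(),
        source=read.source.copy(),
        barcode=read.barcode,
        insertions=list(read.insertions),
    )


def _event_weights(read: ReadRecord | ScoredRead, method: str) -> np.ndarray:
    if method == "none":
        return np.ones(len(read.positions))
    if method == "guppy":
        if np.any(read.qscores < 0):
            raise ValueError(
                f"read {read.read_id} has unscored deletions; "
                "run assign_deletion_qscores first"
            )
        return p_guppy(read.qscores.astype(float))
    if method == "single":
        if not hasattr(read, "p_right"):
            raise ValueError("method 'single' requires model-scored reads")
        return read.p_right
    raise ValueError(f"unknown consensus method {method!r}; choose from {METHODS}")


def weighted_consensus(
    reads: Sequence[ReadRecord | ScoredRead],
    reference: ReferenceSequence,
    method: str = "single",
    sort_homopolymers: bool | None = None,
    group_id: str | None = None,
) -> ConsensusResult:
    """Per-position weighted vote over a group of reads of one variant.

    The winner at each position is the symbol with the largest summed
    weight. Ties prefer the reference symbol, then the lexicographically
    first symbol (A<C<G<T<deletion). Positions covered by no read take
    the reference base, flagged in ``no_coverage``. Homopolymer-deletion
    sorting defaults to on for the recalibrated method only, where it
    helps; it degrades the unrecalibrated ones.
    """
    if not reads:
        raise ValueError("empty read group")
    if sort_homopolymers is None:
        sort_homopolymers = method == "single"
    if sort_homopolymers:
        reads = sort_homopolymer_deletions(reads, reference)
    L = len(reference)
    weights = np.zeros((L, len(SYMBOLS)))
    coverage = np.zeros(L, dtype=np.int64)
    for read in reads:
        w = _event_weights(read, method)
        np.add.at(weights, (read.positions, read.symbols), w)
        np.add.at(coverage, read.positions, 1)
    winners = _resolve_winners(weights, reference.codes)
    no_coverage = coverage == 0
    winners[no_coverage] = reference.codes[no_coverage]
    result = ConsensusResult(
        group_id=group_id,
        method=method,
        winners=winners,
        weights=weights,
        coverage=coverage,
        no_coverage=no_coverage,
    )
    result.sequence = "".join(BASES[c] for c in winners[winners != DEL])
    result.diffs = diff_to_reference(winners, reference)
    return result


def _resolve_winners(weights: np.ndarray, ref_codes: np.ndarray) -> np.ndarray:
    best = weights.max(axis=1)
    # argmax already breaks exact ties toward the lowest symbol index
    winners = np.argmax(weights, axis=1).astype(np.uint8)
    ref_weight = weights[np.arange(len(ref_codes)), ref_codes]
    winners[ref_weight >= best] = ref_codes[ref_weight >= best]
    return winners


def diff_to_reference(
    winners: np.ndarray,
    reference: ReferenceSequence,
) -> list[str]:
    """Mutation labels of a consensus vs. the reference, 1-based.

    Substitutions are labelled refBase+position+altBase ("G23A"),
    deletions "del" + position ("del1320").
    """
    labels = []
    for p in np.flatnonzero(winners != reference.codes):
        w = winners[p]
        if w == DEL:
            labels.append(f"del{p + 1}")
        else:
            labels.append(f"{BASES[reference.codes[p]]}{p + 1}{BASES[w]}")
    return labels


def parse_mutation_label(label: str) -> tuple[int, int]:
    """Inverse of the labelling: returns (0-based position, symbol code)."""
    if label.startswith("del"):
        return int(label[3:]) - 1, DEL
    return int(label[1:-1]) - 1, SYMBOLS.index(label[-1])
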