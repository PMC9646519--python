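"""Position/nucleotide/strand-specific nanopore error model.

The model is trained on reads of a known wild-type amplicon, where every
mismatch to the reference is by construction a sequencing error. For each
reference position p, each non-reference symbol n (the three alternative
bases plus deletion) and each sequencing strand, the Qscore distributions
of correct calls and of errors are combined with two priors —

* ``p_prior_right(r -> n)``: the a-priori probability that position p
  (reference base r) truly mutated to n, derived from the mutagenesis
  spectrum m_{n->n'} and the expected mutation load <m> per read;
* ``p_prior_error(p, n, strand)``: the empirical, Qscore-independent
  error rate of symbol n at that position in the wild-type reads —

into the posterior probability that an observed call of n with Qscore Q
is a genuine mutation::

    P_mutation(Q) = [counts(Q) / sum_Q' counts(Q')] * p_prior_error
    P_wildtype(Q) = [counts_wt(Q) / sum_Q' counts_wt(Q')] * p_prior_right
    N_correct(Q)  = P_wildtype(Q) / (P_wildtype(Q) + P_mutation(Q))

A weighted binomial logistic regression of N_correct on Q is fitted per
cell, yielding a grid of L x 4 x 2 two-parameter regressions (13,296
cells for a 1,662-nt gene). Degenerate cells fall through a documented
fallback chain so every cell stays scorable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import (
    BASES,
    DEL,
    EPSILON,
    FORWARD,
    REVERSE,
    STRAND_NAMES,
    SYMBOLS,
    clamp_prob,
    logit,
    sigmoid,
)
from .io_align import ReadRecord, ReferenceSequence

logger = logging.getLogger(__name__)

QMAX = 50  # largest Phred value kept in count tables

STATUS_OK = "ok"
STATUS_CONSTANT = "fallback_constant"
STATUS_POOLED = "fallback_pooled"
STATUS_PRIOR = "fallback_prior"
_STATUS_CODES = (STATUS_OK, STATUS_CONSTANT, STATUS_POOLED, STATUS_PRIOR)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class QscoreCountTable:
    """counts[p, strand, symbol, Q]: observations in wild-type training reads."""

    counts: np.ndarray  # (L, 2, 5, QMAX+1) int64
    n_reads: int

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    def coverage(self, ref_pos: int | None = None, strand: int | None = None) -> np.ndarray:
        """Reads covering each (position, strand): sum over symbols and Q."""
        cov = self.counts.sum(axis=(2, 3))
        if ref_pos is None:
            return cov
        return cov[ref_pos] if strand is None else cov[ref_pos, strand]

    def zero_coverage_positions(self) -> np.ndarray:
        """(position, strand) pairs never observed during training."""
        return np.argwhere(self.coverage() == 0)


def count_qscores(
    wt_records: Iterable[ReadRecord],
    reference: ReferenceSequence,
    qmax: int = QMAX,
) -> QscoreCountTable:
    """Tally (position, strand, symbol, Qscore) over filtered wild-type reads.

    Deletion events must already carry their neighbour-minimum Qscore
    (see :func:`singlerecall.rescoring.assign_deletion_qscores`).
    """
    L = len(reference)
    counts = np.zeros((L, 2, len(SYMBOLS), qmax + 1), dtype=np.int64)
    n_reads = 0
    for rec in wt_records:
        if rec.positions.size and rec.positions[-1] >= L:
            raise ValueError(f"read {rec.read_id} extends beyond reference length {L}")
        if np.any(rec.qscores < 0):
            raise ValueError(
                f"read {rec.read_id} has unscored deletion events; "
                "run assign_deletion_qscores first"
            )
        q = np.minimum(rec.qscores.astype(np.int64), qmax)
        np.add.at(counts, (rec.positions, rec.strand, rec.symbols, q), 1)
        n_reads += 1
    if n_reads == 0:
        raise ValueError("no wild-type reads supplied")
    table = QscoreCountTable(counts=counts, n_reads=n_reads)
    n_zero = len(table.zero_coverage_positions())
    if n_zero:
        logger.warning("%d (position, strand) cells have zero training coverage", n_zero)
    return table


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class MutationRateMatrix:
    """Relative mutagenesis spectrum m_{n->n'} plus the expected load <m>.

    ``rates`` holds the 12 substitution rates (diagonal zero); ``del_rates``
    optionally extends the spectrum with per-base deletion rates m(n->del)
    for protocols that produce deletions (default zero). ``mean_mutations``
    is the expected number of mutations per sequence, e.g. from an epPCR
    kit datasheet.
    """

    rates: np.ndarray  # (4, 4), diagonal zero
    mean_mutations: float
    del_rates: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.del_rates = np.asarray(self.del_rates, dtype=float)
        if self.rates.shape != (4, 4):
            raise ValueError("rates must be a 4x4 matrix")
        if np.any(np.diag(self.rates) != 0):
            raise ValueError("diagonal (n->n) rates must be zero")
        if np.any(self.rates < 0) or np.any(self.del_rates < 0):
            raise ValueError("rates must be non-negative")
        if not (self.rates.sum() + self.del_rates.sum()) > 0:
            raise ValueError("at least one rate must be positive")
        if not self.mean_mutations > 0:
            raise ValueError("mean_mutations must be positive")

    def full(self) -> np.ndarray:
        """(4, 5) matrix over target symbols A,C,G,T,del."""
        return np.column_stack([self.rates, self.del_rates])

    @classmethod
    def from_tsv(cls, path: str | Path, mean_mutations: float | None = None) -> "MutationRateMatrix":
        """Read a spectrum TSV (columns from_base, to_base, rate).

        ``to_base`` may be '-' or 'del' for deletions. ``mean_mutations``
        may alternatively come from a ``# mean_mutations = X`` header line.
        """
        header_mm = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "mean_mutations" in line:
                    header_mm = float(line.split("=")[-1])
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        rates = np.zeros((4, 4))
        dels = np.zeros(4)
        for row in df.itertuples(index=False):
            i = BASES.index(str(row.from_base).upper())
            to = str(row.to_base).upper()
            if to in ("-", "DEL"):
                dels[i] = float(row.rate)
            else:
                rates[i, BASES.index(to)] = float(row.rate)
        mm = mean_mutations if mean_mutations is not None else header_mm
        if mm is None:
            raise ValueError("mean_mutations not given and not present in the file header")
        return cls(rates=rates, mean_mutations=mm, del_rates=dels)

    @classmethod
    def uniform(cls, mean_mutations: float) -> "MutationRateMatrix":
        rates = np.ones((4, 4)) - np.eye(4)
        return cls(rates=rates, mean_mutations=mean_mutations)


@dataclass
class PriorTable:
    """Both priors of the model.

    ``p_prior_right[r, n]``: probability that a given reference position
    with base r truly mutated to symbol n (n over A,C,G,T,del).
    ``p_prior_error[p, strand, n]``: empirical error fraction of symbol n
    at position p on that strand in the wild-type set; NaN where the
    training coverage was zero (flagged, never silently zero).
    """

    p_prior_right: np.ndarray  # (4, 5)
    p_prior_error: np.ndarray | None = None  # (L, 2, 5)


def compute_prior_right(matrix: MutationRateMatrix, reference: ReferenceSequence) -> PriorTable:
    """Convert the relative spectrum into per-site mutation probabilities.

    p_prior_right(n->n') = m_{n->n'} * <m> / [sum_n counts_ref(n) * sum_n' m_{n->n'}]

    so that summing counts_ref(n) * p_prior_right(n->n') over all cells
    recovers <m> exactly (expected mutation count is conserved).
    """
    m = matrix.full()  # (4, 5)
    counts_ref = reference.base_counts().astype(float)
    denom = float(counts_ref @ m.sum(axis=1))
    if denom <= 0:
        raise ValueError("mutation-rate matrix has no positive rate on reference bases")
    p = m * matrix.mean_mutations / denom
    if np.any(p > 1):
        raise ValueError("p_prior_right exceeds 1; mean_mutations too large for this reference")
    return PriorTable(p_prior_right=p)


def compute_prior_error(table: QscoreCountTable, reference: ReferenceSequence) -> np.ndarray:
    """Per-(position, strand, symbol) empirical error fraction, NaN when uncovered."""
    totals = table.counts.sum(axis=3).astype(float)  # (L, 2, 5)
    cov = totals.sum(axis=2)  # (L, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = totals / cov[:, :, None]
    p[cov == 0] = np.nan
    # the reference symbol's own column is not an error rate
    idx = np.arange(table.L)
    for s in (FORWARD, REVERSE):
        p[idx, s, reference.codes] = np.nan
    return p


def build_priors(
    table: QscoreCountTable,
    matrix: MutationRateMatrix,
    reference: ReferenceSequence,
) -> PriorTable:
    priors = compute_prior_right(matrix, reference)
    priors.p_prior_error = compute_prior_error(table, reference)
    return priors


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------

@dataclass
class ReweightedCell:
    """Prior-adjusted per-Q data for one (position, symbol, strand) cell."""

    ref_pos: int
    symbol: int
    strand: int
    qs: np.ndarray  # defined integer Q bins
    n_correct: np.ndarray  # N_correct(Q) in [0, 1] at the defined bins
    weights: np.ndarray  # effective counts per bin for the regression
    p_mutation: np.ndarray
    p_wildtype: np.ndarray
    defined: bool  # False when the cell has no usable data


def reweight(
    table: QscoreCountTable,
    priors: PriorTable,
    ref_pos: int,
    symbol: int,
    strand: int,
    reference: ReferenceSequence,
) -> ReweightedCell:
    """Build the prior-reweighted response N_correct(Q) for one cell.

    Q bins observed in neither class are flagged as undefined (excluded),
    never zero-filled. The regression weight of a bin is its share of the
    reweighted mass, scaled to the cell's total observation count, so the
    binomial fit sees effective counts on the original scale.
    """
    r = int(reference.codes[ref_pos])
    if symbol == r:
        raise ValueError("reweight is defined for non-reference symbols only")
    c_mut = table.counts[ref_pos, strand, symbol].astype(float)
    c_wt = table.counts[ref_pos, strand, r].astype(float)
    qs_all = np.arange(table.counts.shape[3])
    total_mut, total_wt = c_mut.sum(), c_wt.sum()
    empty = ReweightedCell(
        ref_pos, symbol, strand,
        qs=np.empty(0, int), n_correct=np.empty(0), weights=np.empty(0),
        p_mutation=np.empty(0), p_wildtype=np.empty(0), defined=False,
    )
    if total_mut == 0 and total_wt == 0:
        return empty
    p_err = priors.p_prior_error[ref_pos, strand, symbol]
    if np.isnan(p_err):
        return empty
    p_right = priors.p_prior_right[r, symbol]
    dist_mut = c_mut / total_mut if total_mut > 0 else np.zeros_like(c_mut)
    dist_wt = c_wt / total_wt if total_wt > 0 else np.zeros_like(c_wt)
    p_mut = dist_mut * p_err
    p_wt = dist_wt * p_right
    observed = (c_mut + c_wt) > 0
    mass = p_mut + p_wt
    defined = observed & (mass > 0)
    if not np.any(defined):
        # e.g. zero prior on both classes: no reweighted signal at all
        return empty
    n_correct = p_wt[defined] / mass[defined]
    total_n = total_mut + total_wt
    weights = mass[defined] / mass[defined].sum() * total_n
    return ReweightedCell(
        ref_pos, symbol, strand,
        qs=qs_all[defined], n_correct=n_correct, weights=weights,
        p_mutation=p_mut[defined], p_wildtype=p_wt[defined], defined=True,
    )


# ---------------------------------------------------------------------------
# per-cell weighted binomial logistic fit
# ---------------------------------------------------------------------------

def _newton_logistic(
    q: np.ndarray, y: np.ndarray, w: np.ndarray,
    max_iter: int = 60, tol: float = 1e-12, coef_bound: float = 200.0,
) -> tuple[float, float] | None:
    """Damped Newton MLE of a weighted binomial logistic fit of y on q.

    Returns None when the likelihood has no finite maximiser (perfect
    separation drives the coefficients to the bound) or Newton fails to
    converge. Response values y are proportions in [0, 1]; w are
    effective bin counts.
    """
    qc = q - q.mean()  # center for conditioning; un-shift at the end
    X = np.column_stack([np.ones_like(qc, dtype=float), qc])
    beta = np.zeros(2)
    ybar = np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12)
    beta[0] = float(logit(ybar))
    for _ in range(max_iter):
        eta = X @ beta
        p = sigmoid(eta)
        grad = X.T @ (w * (y - p))
        hess_w = w * p * (1 - p)
        if np.all(hess_w < 1e-14):
            break
        H = X.T @ (X * hess_w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            return None
        # step-halving on the penalised objective (log-likelihood)
        ll0 = _binom_ll(y, w, X @ beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _binom_ll(y, w, X @ cand) >= ll0 - 1e-14:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.abs(np.concatenate([grad, scale * step])).max() < tol * (1 + np.abs(beta).max()):
            break
        if np.abs(beta).max() > coef_bound:
            return None
    else:
        if np.abs(X.T @ (w * (y - sigmoid(X @ beta)))).max() > 1e-6 * max(1.0, w.sum()):
            return None
    if np.abs(beta).max() > coef_bound:
        return None
    b1 = float(beta[1])
    b0 = float(beta[0] - b1 * q.mean())
    return b0, b1


def _binom_ll(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    # weighted binomial log-likelihood up to a constant; stable via logaddexp
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_cell(
    cell: ReweightedCell,
    epsilon: float = EPSILON,
) -> tuple[float, float, str]:
    """Fit N_correct(Q) by weighted binomial logistic regression.

    Returns (b0, b1, status). A proper two-parameter maximum-likelihood
    fit gets status "ok"; flat or separated data collapse to the constant
    maximum-likelihood predictor (b1 = 0, status "fallback_constant"),
    clamped into [epsilon, 1 - epsilon]. A cell without usable data
    signals the caller to use the pooled/prior fallback chain by raising.
    """
    if not cell.defined:
        raise ValueError("cell has no usable data; use the pooled/prior fallback")
    pos = cell.weights > 0
    q, y, w = cell.qs[pos].astype(float), cell.n_correct[pos], cell.weights[pos]
    mean_y = float(np.average(y, weights=w))
    constant = (float(logit(clamp_prob(mean_y, epsilon))), 0.0, STATUS_CONSTANT)
    if len(np.unique(q)) < 2 or np.ptp(y) < 1e-12:
        return constant
    fit = _newton_logistic(q, y, w)
    if fit is None:
        return constant
    return fit[0], fit[1], STATUS_OK


# ---------------------------------------------------------------------------
# the trained model
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


@dataclass
class FitModel:
    """The trained grid of per-(position, symbol, strand) logistic fits.

    Arrays are indexed [position, strand, symbol]; entries at the
    reference base itself are unused (NaN coefficients). Every one of the
    L x 4 x 2 non-reference cells carries coefficients and a status, so
    any event is scorable.
    """

    reference_name: str
    reference_checksum: str
    L: int
    ref_codes: np.ndarray  # (L,) uint8
    b0: np.ndarray  # (L, 2, 5)
    b1: np.ndarray  # (L, 2, 5)
    status: np.ndarray  # (L, 2, 5) uint8 index into _STATUS_CODES; 255 unused
    epsilon: float = EPSILON
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        """Number of fitted regressions: L x 4 symbols x 2 strands."""
        return int(np.sum(self.status != 255))

    def cell(self, ref_pos: int, symbol: int, strand: int) -> tuple[float, float, str]:
        code = self.status[ref_pos, strand, symbol]
        if code == 255:
            raise KeyError("no model cell for the reference base itself")
        return (
            float(self.b0[ref_pos, strand, symbol]),
            float(self.b1[ref_pos, strand, symbol]),
            _STATUS_CODES[code],
        )

    def predict(self, ref_pos, strand, symbol, qscore) -> np.ndarray:
        """p_right of non-reference symbol(s) at the given Qscore(s), clamped."""
        b0 = self.b0[ref_pos, strand, symbol]
        b1 = self.b1[ref_pos, strand, symbol]
        return clamp_prob(sigmoid(b0 + b1 * np.asarray(qscore, dtype=float)), self.epsilon)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as a JSON-headed TSV (one row per cell)."""
        path = Path(path)
        head = {
            "format_version": MODEL_FORMAT_VERSION,
            "reference_name": self.reference_name,
            "reference_checksum": self.reference_checksum,
            "L": self.L,
            "reference_bases": "".join(BASES[c] for c in self.ref_codes),
            "epsilon": self.epsilon,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(head) + "\n")
            fh.write("position\tstrand\tsymbol\tb0\tb1\tstatus\n")
            for p in range(self.L):
                for s in (FORWARD, REVERSE):
                    for n in range(len(SYMBOLS)):
                        code = self.status[p, s, n]
                        if code == 255:
                            continue
                        fh.write(
                            f"{p + 1}\t{STRAND_NAMES[s]}\t{SYMBOLS[n]}\t"
                            f"{float(self.b0[p, s, n])!r}\t{float(self.b1[p, s, n])!r}\t"
                            f"{_STATUS_CODES[code]}\n"
                        )

    @classmethod
    def load(cls, path: str | Path) -> "FitModel":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError(f"{path} is not a model file (missing JSON header)")
            head = json.loads(first[1:])
            if head.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValueError(f"unsupported model format version in {path}")
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        L = int(head["L"])
        from ._util import encode_bases

        ref_codes = encode_bases(head["reference_bases"])
        b0 = np.full((L, 2, len(SYMBOLS)), np.nan)
        b1 = np.full((L, 2, len(SYMBOLS)), np.nan)
        status = np.full((L, 2, len(SYMBOLS)), 255, dtype=np.uint8)
        p = df["position"].to_numpy() - 1
        s = np.array([0 if x == "+" else 1 for x in df["strand"]])
        n = np.array([SYMBOLS.index(x) for x in df["symbol"]])
        b0[p, s, n] = df["b0"].to_numpy(float)
        b1[p, s, n] = df["b1"].to_numpy(float)
        status[p, s, n] = [_STATUS_CODES.index(x) for x in df["status"]]
        return cls(
            reference_name=head["reference_name"],
            reference_checksum=head["reference_checksum"],
            L=L,
            ref_codes=ref_codes,
            b0=b0,
            b1=b1,
            status=status,
            epsilon=float(head["epsilon"]),
            metadata=head.get("metadata", {}),
        )


def _pooled_fit(
    table: QscoreCountTable,
    priors: PriorTable,
    reference: ReferenceSequence,
    symbol: int,
    strand: int,
    epsilon: float,
) -> tuple[float, float, str] | None:
    """Fit one regression pooling every position's reweighted data for
    a (symbol, strand) pair; used for cells with no per-position data."""
    rows_q, rows_y, rows_w = [], [], []
    for p in range(len(reference)):
        if reference.codes[p] == symbol:
            continue
        cell = reweight(table, priors, p, symbol, strand, reference)
        if cell.defined:
            rows_q.append(cell.qs)
            rows_y.append(cell.n_correct)
            rows_w.append(cell.weights)
    if not rows_q:
        return None
    pooled = ReweightedCell(
        -1, symbol, strand,
        qs=np.concatenate(rows_q),
        n_correct=np.concatenate(rows_y),
        weights=np.concatenate(rows_w),
        p_mutation=np.empty(0), p_wildtype=np.empty(0), defined=True,
    )
    b0, b1, status = fit_cell(pooled, epsilon)
    return b0, b1, STATUS_POOLED if status in (STATUS_OK, STATUS_CONSTANT) else status


def train(
    wt_records: Sequence[ReadRecord],
    reference: ReferenceSequence,
    matrix: MutationRateMatrix,
    epsilon: float = EPSILON,
    min_reads: int = 50,
    qmax: int = QMAX,
) -> FitModel:
    """Train the full grid of regressions from filtered wild-type reads.

    Every (position, non-reference symbol, strand) cell receives
    coefficients: a per-cell fit where the reweighted data support one,
    otherwise a pooled fit across positions for that (symbol, strand),
    otherwise a prior-only constant predictor.
    """
    wt_records = list(wt_records)
    if len(wt_records) < min_reads:
        logger.warning(
            "only %d wild-type reads (< %d); the fitted error model may be noisy",
            len(wt_records), min_reads,
        )
    table = count_qscores(wt_records, reference, qmax=qmax)
    priors = build_priors(table, matrix, reference)
    L = len(reference)
    b0 = np.full((L, 2, len(SYMBOLS)), np.nan)
    b1 = np.full((L, 2, len(SYMBOLS)), np.nan)
    status = np.full((L, 2, len(SYMBOLS)), 255, dtype=np.uint8)
    pooled_cache: dict[tuple[int, int], tuple[float, float, str] | None] = {}
    mean_err = np.nanmean(priors.p_prior_error) if np.any(
        ~np.isnan(priors.p_prior_error)
    ) else 0.0
    for p in range(L):
        r = int(reference.codes[p])
        for s in (FORWARD, REVERSE):
            for n in range(len(SYMBOLS)):
                if n == r:
                    continue
                cell = reweight(table, priors, p, n, s, reference)
                if cell.defined:
                    cb0, cb1, st = fit_cell(cell, epsilon)
                else:
                    key = (n, s)
                    if key not in pooled_cache:
                        pooled_cache[key] = _pooled_fit(
                            table, priors, reference, n, s, epsilon
                        )
                    pooled = pooled_cache[key]
                    if pooled is not None:
                        cb0, cb1, st = pooled
                    else:
                        # prior-only constant: posterior of a mutation vs. the
                        # average error rate, ignoring the Qscore entirely
                        pr = priors.p_prior_right[r, n]
                        pe = priors.p_prior_error[p, s, n]
                        if np.isnan(pe):
                            pe = mean_err
                        denom = pr + pe
                        const = pr / denom if denom > 0 else 0.0
                        cb0, cb1, st = float(logit(clamp_prob(const, epsilon))), 0.0, STATUS_PRIOR
                b0[p, s, n] = cb0
                b1[p, s, n] = cb1
                status[p, s, n] = _STATUS_CODES.index(st)
    n_negative = int(np.sum((status <= 1) & (b1 < 0)))
    model = FitModel(
        reference_name=reference.name,
        reference_checksum=reference.checksum,
        L=L,
        ref_codes=reference.codes.copy(),
        b0=b0,
        b1=b1,
        status=status,
        epsilon=epsilon,
        metadata={
            "n_wt_reads": len(wt_records),
            "mean_mutations": matrix.mean_mutations,
            "spectrum": matrix.full().tolist(),
            "qmax": qmax,
            "n_negative_slope_cells": n_negative,
            "status_counts": {
                code: int(np.sum(status == i)) for i, code in enumerate(_STATUS_CODES)
            },
        },
    )
    logger.info(
        "trained %d cells (%s)", model.n_cells,
        ", ".join(f"{k}={v}" for k, v in model.metadata["status_counts"].items()),
    )
    return model
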