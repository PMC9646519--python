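"""Evaluation machinery: signal/noise sweeps, consensus success rates,
positional mismatch skewness and mutational-spectrum correlation.

These reproduce the standard quality measures for reference-anchored
amplicon consensus methods: how well a p_right threshold separates true
mutations from sequencing errors (weighted signal-to-noise and ROC), how
quickly the consensus converges to the true sequence as coverage grows
(success-rate-versus-subset-size, 50 random subsets per size), whether
residual consensus errors concentrate at systematic hotspots (skewness
of the per-position mismatch-count distribution), and whether the
recovered mutations reproduce the mutagenesis spectrum (Pearson r over
the 12 substitution types).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import BASES, DEL, SYMBOLS
from .consensus import parse_mutation_label, weighted_consensus
from .error_model import MutationRateMatrix
from .io_align import ReferenceSequence
from .rescoring import ScoredRead

logger = logging.getLogger(__name__)


def signal_noise(
    scored_reads: Iterable[ScoredRead],
    reference: ReferenceSequence,
    truth_mutations: Iterable[tuple[int, int] | str],
    thresholds: Sequence[float] | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Threshold sweep of weighted true/false mismatch calls.

    ``truth_mutations`` lists the genuine mutations as (0-based position,
    symbol code) pairs or labels like "G23A". For each threshold t,
    signal sums p_right over known-true mismatch events with p_right > t
    and noise over the remaining (error) mismatches; TPR and FPR
    normalise by the total weighted positives/negatives at threshold 0.
    Unweighted counts are reported alongside.
    """
    truth = set()
    for mut in truth_mutations:
        truth.add(parse_mutation_label(mut) if isinstance(mut, str) else (int(mut[0]), int(mut[1])))
    if not truth:
        raise ValueError("empty truth mutation list")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    p_true, p_false = [], []
    for read in scored_reads:
        ref_at = reference.codes[read.positions]
        mism = np.flatnonzero(read.symbols != ref_at)
        for i in mism:
            key = (int(read.positions[i]), int(read.symbols[i]))
            (p_true if key in truth else p_false).append(float(read.p_right[i]))
    p_true = np.asarray(p_true)
    p_false = np.asarray(p_false)
    tot_sig = p_true.sum() if weighted else len(p_true)
    tot_noise = p_false.sum() if weighted else len(p_false)
    rows = []
    for t in thresholds:
        sel_t, sel_f = p_true[p_true > t], p_false[p_false > t]
        sig = sel_t.sum() if weighted else len(sel_t)
        noi = sel_f.sum() if weighted else len(sel_f)
        rows.append({
            "threshold": float(t),
            "signal": float(sig),
            "noise": float(noi),
            "ratio": float(sig / noi) if noi > 0 else np.inf,
            "tpr": float(sig / tot_sig) if tot_sig > 0 else 0.0,
            "fpr": float(noi / tot_noise) if tot_noise > 0 else 0.0,
            "n_true": int(len(sel_t)),
            "n_false": int(len(sel_f)),
        })
    return pd.DataFrame(rows)


def success_rate(
    groups: Mapping[str, Sequence[ScoredRead]],
    truths: Mapping[str, str],
    reference: ReferenceSequence,
    methods: Sequence[str] = ("single", "guppy", "none"),
    subset_sizes: Sequence[int] = tuple(range(3, 51)),
    n_trials: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact-consensus success fraction over random read subsets.

    For each method and subset size, ``n_trials`` subsets are drawn
    without replacement from each group's reads, the consensus computed,
    and compared by exact string equality against the group's true
    sequence. Groups smaller than a subset size are skipped for that
    size with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for method in methods:
        for size in subset_sizes:
            n_success = 0
            n_total = 0
            for gid, reads in groups.items():
                if size > len(reads):
                    logger.warning(
                        "group %s has %d < %d reads; skipped at this size",
                        gid, len(reads), size,
                    )
                    continue
                truth = truths[gid]
                for _ in range(n_trials):
                    idx = rng.choice(len(reads), size=size, replace=False)
                    cons = weighted_consensus(
                        [reads[i] for i in idx], reference, method=method, group_id=gid
                    )
                    n_success += int(cons.sequence == truth)
                    n_total += 1
            if n_total:
                rows.append({
                    "method": method,
                    "subset_size": int(size),
                    "n_trials": n_trials,
                    "n_consensus": n_total,
                    "success": n_success / n_total,
                })
    return pd.DataFrame(rows)


def positional_skewness(
    diffs_per_variant: Iterable[Sequence[str]],
    L: int,
) -> tuple[float, np.ndarray]:
    """Fisher-Pearson skewness of per-position consensus mismatch counts.

    Builds the length-L vector of how many variants' consensus disagrees
    with the reference at each position, and returns its sample skewness
    g1 = m3 / m2^(3/2) (biased moment estimator) together with the count
    vector. A high value marks systematic hotspot positions; mutations
    scattered uniformly give a value near the Poisson-count baseline.
    Undefined (NaN) when there are no mismatches at all.
    """
    counts = np.zeros(L)
    n_variants = 0
    for diffs in diffs_per_variant:
        n_variants += 1
        for label in diffs:
            pos, _ = parse_mutation_label(label)
            counts[pos] += 1
    if n_variants < 2:
        raise ValueError("positional skewness needs at least 2 variants")
    if counts.sum() == 0:
        logger.warning("no consensus mismatches at all; skewness undefined")
        return float("nan"), counts
    if np.ptp(counts) == 0:  # perfectly even counts: symmetric by definition
        return 0.0, counts
    return float(stats.skew(counts, bias=True)), counts


def spectrum_correlation(
    diffs_per_variant: Iterable[Sequence[str]],
    matrix: MutationRateMatrix,
) -> float:
    """Pearson r between observed and expected substitution-type spectra.

    Observed substitution labels are tallied into the 12 (from, to) base
    categories; both the observed frequency vector and the matrix's rate
    vector are normalised to sum 1 before correlating. Deletion labels
    are excluded (the 12-category spectrum covers substitutions). NaN
    (flagged) when fewer than 3 categories were observed or a vector is
    constant.
    """
    observed = np.zeros((4, 4))
    for diffs in diffs_per_variant:
        for label in diffs:
            if label.startswith("del"):
                continue
            i = BASES.index(label[0])
            j = BASES.index(label[-1])
            observed[i, j] += 1
    mask = ~np.eye(4, dtype=bool)
    obs = observed[mask]
    exp = matrix.rates[mask]
    if np.count_nonzero(obs) < 3:
        logger.warning("fewer than 3 substitution categories observed; correlation undefined")
        return float("nan")
    obs = obs / obs.sum()
    exp = exp / exp.sum()
    if np.ptp(obs) == 0 or np.ptp(exp) == 0:
        logger.warning("degenerate (constant) spectrum vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(obs, exp).statistic)
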