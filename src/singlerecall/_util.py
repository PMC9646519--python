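"""Shared encodings and small numeric helpers."""

from __future__ import annotations

import gzip
import hashlib
from pathlib import Path
from typing import IO

import numpy as np

BASES = "ACGT"
DEL = 4  # symbol code for a deletion relative to the reference
GAP_CHAR = "-"
SYMBOLS = BASES + GAP_CHAR  # index == symbol code; A<C<G<T<DEL ordering
SYMBOL_CODE = {c: i for i, c in enumerate(SYMBOLS)}
BASE_CODE = {c: i for i, c in enumerate(BASES)}

FORWARD, REVERSE = 0, 1
STRAND_NAMES = ("+", "-")
STRAND_INDEX = {"+": FORWARD, "-": REVERSE, "forward": FORWARD, "reverse": REVERSE}

#: clamp applied to every model-predicted probability
EPSILON = 1e-6


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes, rejecting anything else."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq):
        code = BASE_CODE.get(c)
        if code is None:
            raise ValueError(f"non-ACGT character {c!r} at position {i + 1}")
        out[i] = code
    return out


def decode_symbols(codes: np.ndarray) -> str:
    return "".join(SYMBOLS[c] for c in codes)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def clamp_prob(p, eps: float = EPSILON):
    return np.clip(p, eps, 1.0 - eps)


def phred_to_perror(q) -> np.ndarray:
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def mean_qscore(qs: np.ndarray) -> float:
    """Mean read quality in the error-probability domain.

    Matches the basecaller summary convention: the per-base error
    probabilities are averaged and converted back to the Phred scale,
    -10*log10(mean(10^(-Q/10))).
    """
    qs = np.asarray(qs, dtype=float)
    if qs.size == 0:
        return 0.0
    return float(-10.0 * np.log10(np.mean(phred_to_perror(qs))))


def sequence_checksum(bases: str) -> str:
    return hashlib.md5(bases.encode("ascii")).hexdigest()


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open a path, transparently handling gzip by suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)
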