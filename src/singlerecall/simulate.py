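"""Synthetic references, error profiles, reads and mutant libraries.

The generator emulates the structure of nanopore amplicon data that the
error model exploits: per-position, per-strand systematic error rates
with a small number of strong hotspots; overlapping Qscore distributions
for correct and erroneous calls (errors emitted with lower quality on
average); deletions, including inside homopolymer runs where their
placement is drawn uniformly; and error-prone-PCR-style variant
libraries with a configurable substitution spectrum, Poisson mutation
load and unique variant barcodes. Every injected event is recorded in a
truth ledger so each downstream module can be tested against known
ground truth, without any external data.

Default error magnitudes follow nanopore's documented behaviour: an
average per-base error of a few percent away from hotspots, and hotspot
positions where one systematic miscall (often a deletion) reaches rates
that corrupt even a majority vote across reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import BASES, DEL, FORWARD, REVERSE, SYMBOLS
from .error_model import MutationRateMatrix
from .io_align import ReadRecord, ReferenceSequence

QLOW, QHIGH = 1, 50  # support of emitted Qscores


def _discrete_normal(mean: float, sd: float) -> np.ndarray:
    """A normal pmf discretised onto integer Q in [QLOW, QHIGH]."""
    qs = np.arange(QLOW, QHIGH + 1)
    pmf = np.exp(-0.5 * ((qs - mean) / sd) ** 2)
    return pmf / pmf.sum()


@dataclass
class ErrorProfile:
    """Systematic per-(position, strand) error structure of a run.

    ``sub_rates[strand, p, b]`` is the probability that a read shows base
    b at position p (zero at the template base itself); ``del_rates`` the
    per-position deletion probability. ``q_correct``/``q_error`` are the
    discrete Qscore emission distributions for correct and erroneous
    calls, deliberately overlapping.
    """

    sub_rates: np.ndarray  # (2, L, 4)
    del_rates: np.ndarray  # (2, L)
    hotspots: np.ndarray  # positions with elevated rates
    q_correct: np.ndarray  # pmf over QLOW..QHIGH
    q_error: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.sub_rates.shape[1]

    def total_rate(self) -> np.ndarray:
        """(2, L) total error probability per covered base."""
        return self.sub_rates.sum(axis=2) + self.del_rates

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sub_rates": self.sub_rates.tolist(),
            "del_rates": self.del_rates.tolist(),
            "hotspots": self.hotspots.tolist(),
            "q_correct": self.q_correct.tolist(),
            "q_error": self.q_error.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            sub_rates=np.asarray(d["sub_rates"]),
            del_rates=np.asarray(d["del_rates"]),
            hotspots=np.asarray(d["hotspots"], dtype=int),
            q_correct=np.asarray(d["q_correct"]),
            q_error=np.asarray(d["q_error"]),
            meta=d.get("meta", {}),
        )


def make_profile(
    reference: ReferenceSequence,
    n_hotspots: int = 5,
    base_error_rate: float = 0.05,
    hotspot_rate: float = 0.40,
    q_correct: tuple[float, float] = (20.0, 4.0),
    q_error: tuple[float, float] = (14.0, 4.0),
    del_fraction: float = 0.4,
    hotspot_del_fraction: float = 0.7,
    hotspot_concentration: float = 0.85,
    seed: int = 0,
) -> ErrorProfile:
    """Draw a reproducible systematic error profile for a reference.

    Away from hotspots, each position's total error rate jitters around
    ``base_error_rate``, split between a deletion share and a per-strand
    random bias over the three alternative bases. Exactly ``n_hotspots``
    positions get ``hotspot_rate`` (slightly jittered per strand),
    concentrated on a single systematic symbol shared by both strands —
    a deletion with probability ``hotspot_del_fraction``, otherwise one
    substitution. The error-call Qscore distribution sits ~6 below the
    correct-call one by default, so the two overlap.
    """
    for name, rate in (("base_error_rate", base_error_rate), ("hotspot_rate", hotspot_rate)):
        if not 0 <= rate <= 0.5:
            raise ValueError(f"{name} must lie in [0, 0.5], got {rate}")
    L = len(reference)
    if n_hotspots > L:
        raise ValueError("more hotspots than positions")
    rng = np.random.default_rng(seed)
    sub = np.zeros((2, L, 4))
    dele = np.zeros((2, L))
    alt = np.array([[b for b in range(4) if b != r] for r in reference.codes])  # (L, 3)
    for s in (FORWARD, REVERSE):
        total = base_error_rate * rng.uniform(0.5, 1.5, size=L)
        dele[s] = total * del_fraction * rng.uniform(0.5, 1.5, size=L)
        sub_total = total - dele[s]
        split = rng.dirichlet(np.ones(3) * 2.0, size=L)  # per-strand systematic bias
        np.put_along_axis(sub[s], alt, split * sub_total[:, None], axis=1)
    hotspots = np.sort(rng.choice(L, size=n_hotspots, replace=False))
    for p in hotspots:
        if rng.uniform() < hotspot_del_fraction:
            target = DEL
        else:
            target = int(rng.choice(alt[p]))
        for s in (FORWARD, REVERSE):
            # one systematic miscall (shared by both strands) takes most of
            # the hotspot's rate; the remainder spreads over the other errors
            rate = min(hotspot_rate * rng.uniform(0.9, 1.1), 0.5)
            spread = (1 - hotspot_concentration) * rate / 3
            sub[s, p, :] = 0.0
            sub[s, p, alt[p]] = spread
            dele[s, p] = spread
            if target == DEL:
                dele[s, p] = hotspot_concentration * rate
            else:
                sub[s, p, target] = hotspot_concentration * rate
    profile = ErrorProfile(
        sub_rates=sub,
        del_rates=dele,
        hotspots=hotspots,
        q_correct=_discrete_normal(*q_correct),
        q_error=_discrete_normal(*q_error),
        meta={
            "n_hotspots": n_hotspots,
            "base_error_rate": base_error_rate,
            "hotspot_rate": hotspot_rate,
            "q_correct": list(q_correct),
            "q_error": list(q_error),
            "seed": seed,
        },
    )
    assert np.all(profile.total_rate() <= 0.5 + 1e-9)
    return profile


@dataclass
class Variant:
    variant_id: str
    barcode: str
    symbols: np.ndarray  # (L,) template symbol per reference position (may contain DEL)
    mutations: list[str]  # labels, e.g. "G23A", "del17"


@dataclass
class TruthLedger:
    """Ground truth of a simulation: variants and every injected error."""

    reference: str
    variants: dict[str, dict] = field(default_factory=dict)  # id -> {barcode, mutations}
    reads: dict[str, dict] = field(default_factory=dict)  # id -> {variant, strand, errors}

    def record_variant(self, v: Variant) -> None:
        self.variants[v.variant_id] = {"barcode": v.barcode, "mutations": list(v.mutations)}

    def record_read(self, read_id: str, variant_id: str, strand: int,
                    errors: list[tuple[int, int, int]]) -> None:
        self.reads[read_id] = {
            "variant": variant_id,
            "strand": "+-"[strand],
            "errors": [[int(p), SYMBOLS[s], int(q)] for p, s, q in errors],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"reference": self.reference, "variants": self.variants, "reads": self.reads}
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        d = json.loads(Path(path).read_text())
        return cls(reference=d["reference"], variants=d["variants"], reads=d["reads"])


def random_reference(L: int, seed: int = 0, name: str = "ref") -> ReferenceSequence:
    rng = np.random.default_rng(seed)
    return ReferenceSequence(name=name, bases="".join(rng.choice(list(BASES), size=L)))


def random_barcodes(n: int, length: int = 36, seed: int = 0) -> list[str]:
    """Unique random barcodes (36 nt by default, as in barcoded libraries)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice(list(BASES), size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_variants(
    reference: ReferenceSequence,
    matrix: MutationRateMatrix,
    n_variants: int,
    seed: int = 0,
    barcode_length: int = 36,
) -> list[Variant]:
    """Draw an epPCR-style library: Poisson(<m>) mutations per variant,
    positions uniform, substitution identity proportional to m_{n->n'}
    given the template base (deletions included when the matrix carries
    deletion rates)."""
    rng = np.random.default_rng(seed)
    m = matrix.full()  # (4, 5)
    barcodes = random_barcodes(n_variants, barcode_length, seed=rng.integers(2**31))
    variants = []
    L = len(reference)
    for i in range(n_variants):
        k = rng.poisson(matrix.mean_mutations)
        symbols = reference.codes.astype(np.uint8).copy()
        chosen: set[int] = set()
        labels = []
        attempts = 0
        while len(chosen) < min(k, L) and attempts < 50 * max(k, 1):
            attempts += 1
            p = int(rng.integers(L))
            if p in chosen:
                continue
            row = m[reference.codes[p]]
            if row.sum() <= 0:
                continue  # this base cannot mutate under the spectrum
            target = int(rng.choice(len(SYMBOLS), p=row / row.sum()))
            chosen.add(p)
            symbols[p] = target
            if target == DEL:
                labels.append(f"del{p + 1}")
            else:
                labels.append(f"{BASES[reference.codes[p]]}{p + 1}{BASES[target]}")
        labels.sort(key=lambda s: int("".join(c for c in s if c.isdigit())))
        variants.append(Variant(
            variant_id=f"v{i:04d}", barcode=barcodes[i], symbols=symbols, mutations=labels,
        ))
    return variants


def simulate_reads(
    template: np.ndarray | ReferenceSequence,
    profile: ErrorProfile,
    n_reads: int,
    strand_mix: float = 0.5,
    seed: int = 0,
    read_prefix: str = "read",
    variant_id: str = "wt",
    barcode: str | None = None,
    ledger: TruthLedger | None = None,
) -> list[ReadRecord]:
    """Emit full-length reads of a template with profile-driven errors.

    ``template`` is a per-reference-position symbol array (a true
    deletion in the template yields a deletion event in every read).
    Errors are injected independently per covered position: a deletion
    or a substitution to a base drawn from the profile's systematic
    rates (relative to the reference frame); correct calls draw their
    Qscore from the correct-call distribution, errors from the error
    one. Deletion events carry no Qscore at this stage.
    """
    if isinstance(template, ReferenceSequence):
        template = template.codes
    template = np.asarray(template, dtype=np.uint8)
    L = profile.L
    if len(template) != L:
        raise ValueError("template length does not match the profile")
    rng = np.random.default_rng(seed)
    qs_support = np.arange(QLOW, QHIGH + 1)
    positions = np.arange(L, dtype=np.int32)
    reads = []
    for i in range(n_reads):
        strand = REVERSE if rng.uniform() < (1 - strand_mix) else FORWARD
        u = rng.uniform(size=L)
        symbols = template.copy()
        # thresholds: [0, del) -> deletion, [del, del+sub_k) -> substitution
        dele = profile.del_rates[strand]
        cum = np.cumsum(profile.sub_rates[strand], axis=1)  # (L, 4)
        is_del = u < dele
        symbols[is_del] = DEL
        rem = u - dele
        sub_hit = (~is_del) & (rem < cum[:, 3])
        for p in np.flatnonzero(sub_hit):
            b = int(np.searchsorted(cum[p], rem[p], side="right"))
            if b == template[p]:
                # template differs from reference here; redirect to another base
                b = int(rng.choice([x for x in range(4) if x != template[p]]))
            symbols[p] = b
        true_del = template == DEL
        symbols[true_del] = DEL
        is_error = (symbols != template) & ~true_del
        qscores = np.empty(L, dtype=np.int16)
        qscores[:] = rng.choice(qs_support, size=L, p=profile.q_correct)
        n_err = int(is_error.sum())
        if n_err:
            qscores[is_error] = rng.choice(qs_support, size=n_err, p=profile.q_error)
        qscores[symbols == DEL] = -1
        read_id = f"{read_prefix}{i:05d}"
        rec = ReadRecord(
            read_id=read_id,
            strand=strand,
            positions=positions.copy(),
            symbols=symbols,
            qscores=qscores,
            barcode=barcode,
        )
        reads.append(rec)
        if ledger is not None:
            errors = [
                (int(p), int(symbols[p]), int(qscores[p]))
                for p in np.flatnonzero(is_error)
            ]
            ledger.record_read(read_id, variant_id, strand, errors)
    return reads


@dataclass
class SimulatedExperiment:
    """A full synthetic study: training reads plus a barcoded library."""

    reference: ReferenceSequence
    profile: ErrorProfile
    matrix: MutationRateMatrix
    wt_reads: list[ReadRecord]
    variants: list[Variant]
    library_reads: dict[str, list[ReadRecord]]  # barcode -> reads
    ledger: TruthLedger

    def variant_by_barcode(self, barcode: str) -> Variant:
        for v in self.variants:
            if v.barcode == barcode:
                return v
        raise KeyError(barcode)


# An epPCR-like default spectrum: A/T-biased with a transition preference,
# the shape typical of mutagenesis kit datasheets. Relative rates.
DEFAULT_SPECTRUM = np.array([
    #  to A     C     G     T
    [0.000, 0.040, 0.060, 0.230],  # from A
    [0.050, 0.000, 0.020, 0.140],  # from C
    [0.140, 0.020, 0.000, 0.050],  # from G
    [0.230, 0.060, 0.040, 0.000],  # from T
])


def default_matrix(mean_mutations: float) -> MutationRateMatrix:
    return MutationRateMatrix(rates=DEFAULT_SPECTRUM.copy(), mean_mutations=mean_mutations)


def simulate_experiment(
    L: int = 300,
    n_hotspots: int = 5,
    n_wt_reads: int = 500,
    n_variants: int = 30,
    reads_per_variant: int = 20,
    mean_mutations: float = 2.0,
    matrix: MutationRateMatrix | None = None,
    seed: int = 1,
    **profile_kwargs,
) -> SimulatedExperiment:
    """Generate the standard synthetic study: a random reference, its
    systematic error profile, wild-type training reads, and a barcoded
    variant library with per-read ground truth."""
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31, size=4 + n_variants)
    reference = random_reference(L, seed=int(seeds[0]))
    profile = make_profile(reference, n_hotspots=n_hotspots, seed=int(seeds[1]), **profile_kwargs)
    matrix = matrix if matrix is not None else default_matrix(mean_mutations)
    ledger = TruthLedger(reference=reference.bases)
    wt_reads = simulate_reads(
        reference, profile, n_wt_reads, seed=int(seeds[2]),
        read_prefix="wt", variant_id="wt", ledger=ledger,
    )
    variants = simulate_variants(reference, matrix, n_variants, seed=int(seeds[3]))
    library: dict[str, list[ReadRecord]] = {}
    for i, v in enumerate(variants):
        ledger.record_variant(v)
        library[v.barcode] = simulate_reads(
            v.symbols, profile, reads_per_variant, seed=int(seeds[4 + i]),
            read_prefix=f"{v.variant_id}_r", variant_id=v.variant_id,
            barcode=v.barcode, ledger=ledger,
        )
    return SimulatedExperiment(
        reference=reference,
        profile=profile,
        matrix=matrix,
        wt_reads=wt_reads,
        variants=variants,
        library_reads=library,
        ledger=ledger,
    )
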