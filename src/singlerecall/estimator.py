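"""Estimator-style facade over the trainable error model.

`SingleErrorModel` follows the fit/transform idiom: hyperparameters in
``__init__`` (inspectable via ``get_params``/``set_params``), data in
``fit``, fitted state in trailing-underscore attributes. The inputs are
alignment event streams rather than feature matrices, so the class does
not pretend to be a drop-in sklearn transformer, but it composes the
same way: fit once on wild-type reads, then transform any number of
variant read sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .error_model import EPSILON, FitModel, MutationRateMatrix, QMAX, train
from .io_align import ReadRecord, ReferenceSequence
from .rescoring import ScoredRead, assign_deletion_qscores, score_read


class SingleErrorModel:
    """Position/nucleotide/strand-specific Qscore recalibration model.

    Parameters
    ----------
    epsilon:
        Clamp applied to every predicted probability, keeping weights
        strictly inside (0, 1).
    min_reads:
        Soft floor on the number of wild-type training reads; fewer
        triggers a warning, not an error.
    qmax:
        Largest Phred value kept in the count tables.
    """

    def __init__(self, epsilon: float = EPSILON, min_reads: int = 50, qmax: int = QMAX):
        self.epsilon = epsilon
        self.min_reads = min_reads
        self.qmax = qmax

    # -- sklearn-style parameter plumbing ----------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {"epsilon": self.epsilon, "min_reads": self.min_reads, "qmax": self.qmax}

    def set_params(self, **params) -> "SingleErrorModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r} for SingleErrorModel")
            setattr(self, k, v)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"SingleErrorModel({args})"

    # -- fitting and scoring ------------------------------------------------

    def fit(
        self,
        wt_records: Sequence[ReadRecord],
        reference: ReferenceSequence,
        matrix: MutationRateMatrix,
    ) -> "SingleErrorModel":
        """Train the regression grid on filtered wild-type reads."""
        records = [assign_deletion_qscores(r) for r in wt_records]
        self.model_ = train(
            records, reference, matrix,
            epsilon=self.epsilon, min_reads=self.min_reads, qmax=self.qmax,
        )
        self.reference_ = reference
        self.n_cells_ = self.model_.n_cells
        return self

    def _check_fitted(self) -> FitModel:
        if not hasattr(self, "model_"):
            raise RuntimeError("SingleErrorModel is not fitted; call fit() first")
        return self.model_

    def transform(self, records: Iterable[ReadRecord]) -> list[ScoredRead]:
        """Attach p_right to every event of the given variant reads."""
        model = self._check_fitted()
        return [
            score_read(assign_deletion_qscores(r), model, self.reference_)
            for r in records
        ]

    def fit_transform(self, wt_records, reference, matrix, records) -> list[ScoredRead]:
        return self.fit(wt_records, reference, matrix).transform(records)

    def predict_p_right(self, ref_pos: int, strand: int, symbol: int, qscore) :
        """Evaluate one model cell at the given Qscore(s)."""
        return self._check_fitted().predict(ref_pos, strand, symbol, qscore)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted().save(path)

    @classmethod
    def from_file(cls, path, reference: ReferenceSequence) -> "SingleErrorModel":
        model = FitModel.load(path)
        if model.reference_checksum != reference.checksum:
            raise ValueError("model file was trained on a different reference")
        est = cls(epsilon=model.epsilon, qmax=model.metadata.get("qmax", QMAX))
        est.model_ = model
        est.reference_ = reference
        est.n_cells_ = model.n_cells
        return est
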