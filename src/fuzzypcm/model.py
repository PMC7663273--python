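"""Integration of positional scores and belonging coefficients into B(C).

Each training sequence k carries two coefficients for a compound C:
a_k, weighting the protein's ability to interact with C, and b_k its
inability.  In BINARY mode the curated interaction index supplies
(a_k, b_k) in {(1,0), (0,1)}, with (0,0) for unmeasured pairs.  In FUZZY
mode the per-target naive-Bayes probabilities substitute them:
a_k = Pa_k(C), b_k = Pi_k(C) — a fuzzy partition of the training set into
interactor and non-interactor classes that requires no measured index for
the query compound.

Per test-sequence position p, with S_pk the positional scores against the
N training sequences,

    t_p = sum_k S_pk (a_k - b_k) / sum_k S_pk (a_k + b_k),
    t   = sin( mean_p arcsin(t_p) ),
    t0  = sum_k (a_k - b_k) / sum_k (a_k + b_k),
    B   = (t - t0) / (1 - t * t0).

B(C) ranges from -1 (no interaction) to +1 (interaction); 0 is the
undetermined result, and a zero denominator in t_p or t0 (no weighted
information at all) is mapped to that neutral 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import copysign
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .bayes import fit_target_model, predict_pa_pi, _as_descriptor_set
from .curation import InteractionDataset
from .scoring import score_matrix

__all__ = [
    "PredictionResult",
    "position_score_tp",
    "aggregate_t",
    "prior_t0",
    "estimate_b",
    "interaction_estimate",
    "binary_coefficients",
    "predict_pair",
    "ProteochemometricPredictor",
]

#: tolerance for |1 - t*t0| below which B saturates to +-1
EPS_SINGULARITY = 1e-12
#: tolerated floating-point excursion of t_p/t/t0 beyond [-1, 1]
EPS_RANGE = 1e-9


@dataclass
class PredictionResult:
    """Outcome of one (test protein, compound) interaction estimate."""

    t_p: np.ndarray
    t: float
    t0: float
    b: float
    m: int
    n_train: int
    protein_id: str | None = None
    ligand_id: str | None = None


def _validate_coeffs(a: np.ndarray, b: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != (n,) or b.shape != (n,):
        raise ValueError(
            f"coefficient vectors of length {a.shape}/{b.shape} do not match {n} scores"
        )
    for name, v in (("a", a), ("b", b)):
        if ((v < -EPS_RANGE) | (v > 1 + EPS_RANGE)).any():
            raise ValueError(f"coefficients {name} must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0), np.clip(b, 0.0, 1.0)


def position_score_tp(scores, a, b) -> float | np.ndarray:
    """Integrated score t_p (Eq. above) for one position or a whole matrix.

    ``scores`` is either the length-N vector S_p. for one position (returns
    a scalar) or an (m, N) matrix (returns the length-m t_p vector).  A zero
    denominator — no training sequence carries any weighted similarity —
    yields the neutral 0.
    """
    s = np.asarray(scores, dtype=np.float64)
    single = s.ndim == 1
    if single:
        s = s[None, :]
    if s.ndim != 2:
        raise ValueError(f"scores must be 1-D or 2-D, got shape {s.shape}")
    if (s < 0).any():
        raise ValueError("positional scores must be nonnegative")
    a, b = _validate_coeffs(a, b, s.shape[1])
    num = s @ (a - b)
    den = s @ (a + b)
    tp = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(tp[0]) if single else tp


def aggregate_t(tp: Sequence[float] | np.ndarray) -> float:
    """Aggregate per-position scores: sine of the mean arcsine."""
    tp = np.asarray(tp, dtype=np.float64)
    if tp.size == 0:
        raise ValueError("cannot aggregate an empty t_p vector")
    if ((tp < -1 - EPS_RANGE) | (tp > 1 + EPS_RANGE)).any():
        raise ValueError("t_p values must lie in [-1, 1]")
    tp = np.clip(tp, -1.0, 1.0)
    return float(np.sin(np.mean(np.arcsin(tp))))


def prior_t0(a, b) -> float:
    """A-priori score: coefficient contrast without sequence similarity."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a, b = _validate_coeffs(a, b, a.shape[0] if a.ndim == 1 else -1)
    den = float((a + b).sum())
    if den <= 0:
        return 0.0
    return float((a - b).sum() / den)


def estimate_b(t: float, t0: float) -> float:
    """Final interaction estimate B = (t - t0) / (1 - t*t0).

    B is 0 whenever t equals t0 (undetermined, including t = t0 = +-1); at
    the hyperbolic singularity |1 - t*t0| < eps with t != t0 it saturates to
    sign(t - t0).
    """
    for name, v in (("t", t), ("t0", t0)):
        if not -1 - EPS_RANGE <= v <= 1 + EPS_RANGE:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    t = min(max(t, -1.0), 1.0)
    t0 = min(max(t0, -1.0), 1.0)
    if t == t0:
        return 0.0
    den = 1.0 - t * t0
    if abs(den) < EPS_SINGULARITY:
        return copysign(1.0, t - t0)
    return (t - t0) / den


def interaction_estimate(
    scores: np.ndarray,
    a,
    b,
    *,
    protein_id: str | None = None,
    ligand_id: str | None = None,
) -> PredictionResult:
    """Apply the full t_p -> t -> t0 -> B chain to an (m, N) score matrix."""
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 2:
        raise ValueError(f"expected an (m, N) score matrix, got shape {s.shape}")
    tp = position_score_tp(s, a, b)
    t = aggregate_t(tp)
    t0 = prior_t0(a, b)
    return PredictionResult(
        t_p=tp,
        t=t,
        t0=t0,
        b=estimate_b(t, t0),
        m=s.shape[0],
        n_train=s.shape[1],
        protein_id=protein_id,
        ligand_id=ligand_id,
    )


def binary_coefficients(
    dataset: InteractionDataset, ligand_id: str, training_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Binary (a_k, b_k) from curated indices: (1,0) for an established
    interactor, (0,1) for an established non-interactor, (0,0) unmeasured."""
    a = np.zeros(len(training_ids))
    b = np.zeros(len(training_ids))
    for col, pid in enumerate(training_ids):
        idx = dataset.indices.get((pid, ligand_id))
        if idx == 1:
            a[col] = 1.0
        elif idx == 0:
            b[col] = 1.0
    return a, b


def predict_pair(
    test_seq: str,
    ligand,
    training: InteractionDataset,
    mode: Literal["binary", "fuzzy"] = "binary",
    *,
    frame: int = 7,
    level: int = 2,
    alpha: float = 1.0,
    exclude_protein: str | None = None,
    protein_id: str | None = None,
) -> PredictionResult:
    """Estimate the interaction of a test sequence with a compound.

    ``ligand`` is a ligand identifier of the training set or (FUZZY mode
    only) any structure accepted by the descriptor layer.  The test protein
    must not be part of the training sequences; pass ``exclude_protein`` to
    hold a dataset protein out.  In FUZZY mode the per-target classifiers
    are fitted with the query compound excluded when it is a training
    ligand.
    """
    train_seqs = {
        pid: seq for pid, seq in training.proteins.items() if pid != exclude_protein
    }
    if not train_seqs:
        raise ValueError("training set is empty after exclusions")
    scores, ids = score_matrix(test_seq, train_seqs, frame)

    ligand_id = ligand if isinstance(ligand, str) and ligand in training.ligands else None
    if mode == "binary":
        if ligand_id is None:
            raise ValueError(
                "BINARY mode requires a ligand identifier with curated indices"
            )
        a, b = binary_coefficients(training, ligand_id, ids)
    elif mode == "fuzzy":
        if ligand_id is not None:
            descriptors = training.ligands[ligand_id].descriptors(level)
        else:
            descriptors = _as_descriptor_set(ligand, level)
        a = np.empty(len(ids))
        b = np.empty(len(ids))
        for col, pid in enumerate(ids):
            model = fit_target_model(
                training, pid, exclude_ligand=ligand_id, alpha=alpha, level=level
            )
            a[col], b[col] = predict_pa_pi(model, descriptors)
    else:
        raise ValueError(f"mode must be 'binary' or 'fuzzy', got {mode!r}")

    return interaction_estimate(
        scores, a, b, protein_id=protein_id or exclude_protein, ligand_id=ligand_id
    )


class ProteochemometricPredictor(BaseEstimator):
    """Protein-ligand interaction predictor over a curated dataset.

    A scikit-learn-style estimator: hyperparameters in ``__init__``,
    ``fit`` on the curated training data, fitted state in trailing-
    underscore attributes, ``predict`` for external (sequence, compound)
    queries.

    Parameters
    ----------
    frame : int
        Segment length F for sequence comparison (7 captures close
        inter-residue context, 30 distant context).
    mode : {"binary", "fuzzy"}
        Source of the belonging coefficients: curated indices or per-target
        naive-Bayes (Pa, Pi).
    level : int
        MNA descriptor depth (fuzzy mode).
    alpha : float
        Laplace smoothing of the per-target classifiers (fuzzy mode).
    """

    def __init__(
        self,
        frame: int = 7,
        mode: Literal["binary", "fuzzy"] = "fuzzy",
        level: int = 2,
        alpha: float = 1.0,
    ):
        self.frame = frame
        self.mode = mode
        self.level = level
        self.alpha = alpha

    def fit(self, dataset: InteractionDataset, y=None) -> "ProteochemometricPredictor":
        """Bind the curated training dataset; fit per-target classifiers in
        fuzzy mode."""
        if self.mode not in ("binary", "fuzzy"):
            raise ValueError(f"mode must be 'binary' or 'fuzzy', got {self.mode!r}")
        if not dataset.proteins:
            raise ValueError("training dataset has no proteins")
        self.dataset_ = dataset
        self.train_ids_ = sorted(dataset.proteins)
        if self.mode == "fuzzy":
            self.target_models_ = {
                pid: fit_target_model(dataset, pid, alpha=self.alpha, level=self.level)
                for pid in self.train_ids_
            }
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "dataset_"):
            raise ValueError("predictor is not fitted; call fit first")

    def predict_one(self, sequence: str, ligand, **ids) -> PredictionResult:
        """Score one external query; ``ligand`` is a dataset ligand id or
        (fuzzy mode) any parseable structure."""
        self._check_fitted()
        scores, train_ids = score_matrix(sequence, self.dataset_.proteins, self.frame)
        if self.mode == "binary":
            if not (isinstance(ligand, str) and ligand in self.dataset_.ligands):
                raise ValueError("BINARY mode requires a training ligand identifier")
            a, b = binary_coefficients(self.dataset_, ligand, train_ids)
            lig_id = ligand
        else:
            lig_id = ligand if isinstance(ligand, str) and ligand in self.dataset_.ligands else None
            if lig_id is not None:
                descriptors = self.dataset_.ligands[lig_id].descriptors(self.level)
            else:
                descriptors = _as_descriptor_set(ligand, self.level)
            a = np.empty(len(train_ids))
            b = np.empty(len(train_ids))
            for col, pid in enumerate(train_ids):
                a[col], b[col] = predict_pa_pi(self.target_models_[pid], descriptors)
        return interaction_estimate(
            scores, a, b, ligand_id=ids.get("ligand_id", lig_id), protein_id=ids.get("protein_id")
        )

    def predict(self, queries) -> list[PredictionResult]:
        """Score an iterable of (sequence, ligand) queries."""
        return [self.predict_one(seq, lig) for seq, lig in queries]
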