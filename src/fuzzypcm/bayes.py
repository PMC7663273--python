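"""Per-target naive-Bayes ligand activity classifier over MNA descriptors.

For one target protein, the curated index-1 ligands form the interacting
(active) class and the index-0 ligands the non-interacting class.  From
per-descriptor membership counts the classifier produces two *independent*
probabilities for any query compound: Pa, the probability that the compound
interacts with the target, and Pi, the probability that it does not.  Pa and
Pi are separate one-vs-rest estimates and need not sum to one.

Estimator.  With n_a active and n_i inactive training ligands and c_a(d),
c_i(d) the numbers of each containing descriptor d, the smoothed
per-descriptor posterior for the active class is

    q_d = (c_a(d) + alpha * p) / (c_a(d) + c_i(d) + alpha),
    p   = (n_a + 1) / (n_a + n_i + 2),

and the naive-Bayes log-odds over the query's descriptors (restricted to
descriptors seen in training) is

    L_a = logit(p) + sum_d [ logit(q_d) - logit(p) ],     Pa = expit(L_a),

with Pi computed symmetrically from the inactive class.  A compound sharing
no descriptor with the training data therefore receives the bare priors.
This posterior-odds form guarantees that a descriptor occurring exclusively
in active training ligands can only raise Pa.  Targets left without one of
the classes (common in sparse curated data) are degenerate: the missing
class's probability falls back to a supplied global prior.

All accumulation orders are lexicographic, so outputs are bit-stable.
"""

from __future__ import annotations

import json
from typing import Iterable, NamedTuple

import numpy as np
from rdkit import Chem
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin

from .curation import InteractionDataset, LigandStructure
from .descriptors import mna_descriptors

__all__ = [
    "PaPiEstimate",
    "MNABayesClassifier",
    "fit_target_model",
    "predict_pa_pi",
    "pa_pi_from_counts",
]


class PaPiEstimate(NamedTuple):
    """Independent interaction / non-interaction probabilities."""

    pa: float
    pi: float


def _as_descriptor_set(x, level: int) -> frozenset[str]:
    if isinstance(x, frozenset):
        return x
    if isinstance(x, (set, list, tuple)):
        return frozenset(x)
    if isinstance(x, LigandStructure):
        return x.descriptors(level)
    if isinstance(x, Chem.Mol):
        return mna_descriptors(x, level)
    if isinstance(x, str):
        mol = Chem.MolFromSmiles(x)
        if mol is None:
            raise ValueError(f"cannot parse SMILES {x!r}")
        return mna_descriptors(mol, level)
    raise TypeError(f"cannot derive descriptors from {type(x).__name__}")


def pa_pi_from_counts(
    descriptors: Iterable[str],
    get_count,
    n_active: int,
    n_inactive: int,
    alpha: float,
    prior_active: float | None = None,
    prior_inactive: float | None = None,
) -> PaPiEstimate:
    """Evaluate (Pa, Pi) from descriptor count statistics.

    ``get_count(d)`` returns ``(c_active, c_inactive)`` for a training-seen
    descriptor or ``None`` for an unseen one (unseen descriptors carry no
    evidence).  Class priors are local Laplace estimates; ``prior_active`` /
    ``prior_inactive`` are fallback constants returned for a class with no
    training members (degenerate target).
    """
    total = n_active + n_inactive
    p_a = (n_active + 1) / (total + 2)
    p_i = (n_inactive + 1) / (total + 2)
    fallback_a = p_a if prior_active is None else prior_active
    fallback_i = p_i if prior_inactive is None else prior_inactive

    evidence: list[tuple[int, int]] = []
    for d in sorted(set(descriptors)):
        cnt = get_count(d)
        if cnt is None:
            continue
        ca, ci = cnt
        if ca == 0 and ci == 0:
            continue  # descriptor seen only in an excluded ligand
        evidence.append((ca, ci))

    if n_active > 0 and n_inactive > 0:
        la = logit(p_a)
        li = logit(p_i)
        for ca, ci in evidence:
            qa = (ca + alpha * p_a) / (ca + ci + alpha)
            qi = (ci + alpha * p_i) / (ca + ci + alpha)
            la += logit(qa) - logit(p_a)
            li += logit(qi) - logit(p_i)
        pa = float(expit(la))
        pi = float(expit(li))
    elif n_active > 0:  # no inactive examples: Pi falls back to the prior
        la = logit(p_a)
        for ca, ci in evidence:
            qa = (ca + alpha * p_a) / (ca + ci + alpha)
            la += logit(qa) - logit(p_a)
        pa = float(expit(la))
        pi = float(fallback_i)
    elif n_inactive > 0:  # no active examples: Pa falls back to the prior
        li = logit(p_i)
        for ca, ci in evidence:
            qi = (ci + alpha * p_i) / (ca + ci + alpha)
            li += logit(qi) - logit(p_i)
        pa = float(fallback_a)
        pi = float(expit(li))
    else:
        pa, pi = float(fallback_a), float(fallback_i)
    return PaPiEstimate(min(max(pa, 0.0), 1.0), min(max(pi, 0.0), 1.0))


class MNABayesClassifier(ClassifierMixin, BaseEstimator):
    """Naive-Bayes activity classifier on MNA descriptor presence.

    Parameters
    ----------
    alpha : float
        Laplace smoothing constant for the per-descriptor posteriors.
    level : int
        MNA neighborhood depth used when inputs are molecules/SMILES.
    prior_active, prior_inactive : float or None
        Global fallback priors used when a class is empty (degenerate
        target); ``None`` uses the Laplace class prior from the fit data.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Always ``[0, 1]`` (non-interacting, interacting).
    counts_ : dict[str, tuple[int, int]]
        Per-descriptor (active, inactive) membership counts.
    n_active_, n_inactive_ : int
        Class sizes.
    degenerate_ : bool
        True when one class is empty after fitting.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        level: int = 2,
        prior_active: float | None = None,
        prior_inactive: float | None = None,
    ):
        self.alpha = alpha
        self.level = level
        self.prior_active = prior_active
        self.prior_inactive = prior_inactive

    def fit(self, X, y) -> "MNABayesClassifier":
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        y = np.asarray(list(y))
        sets = [_as_descriptor_set(x, self.level) for x in X]
        if len(sets) != len(y):
            raise ValueError(f"X and y lengths differ: {len(sets)} vs {len(y)}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1 interaction indices")
        counts: dict[str, list[int]] = {}
        for ds, label in zip(sets, y):
            col = 0 if label == 1 else 1
            for d in ds:
                counts.setdefault(d, [0, 0])[col] += 1
        self.counts_ = {d: (ca, ci) for d, (ca, ci) in counts.items()}
        self.n_active_ = int((y == 1).sum())
        self.n_inactive_ = int((y == 0).sum())
        self.degenerate_ = self.n_active_ == 0 or self.n_inactive_ == 0
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "counts_"):
            raise ValueError("classifier is not fitted; call fit first")

    def predict_pa_pi(self, X) -> np.ndarray:
        """Return an ``(n, 2)`` array of (Pa, Pi) per compound."""
        self._check_fitted()
        out = np.empty((len(X), 2))
        for row, x in enumerate(X):
            est = pa_pi_from_counts(
                _as_descriptor_set(x, self.level),
                self.counts_.get,
                self.n_active_,
                self.n_inactive_,
                self.alpha,
                self.prior_active,
                self.prior_inactive,
            )
            out[row] = est
        return out

    def decision_function(self, X) -> np.ndarray:
        """Pa - Pi ranking score (positive favors interaction)."""
        papi = self.predict_pa_pi(X)
        return papi[:, 0] - papi[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def _global_priors(dataset: InteractionDataset) -> tuple[float, float]:
    """Laplace-smoothed dataset-wide class priors (fallback for degenerate targets)."""
    values = list(dataset.indices.values())
    n_pos = sum(values)
    n = len(values)
    return (n_pos + 1) / (n + 2), (n - n_pos + 1) / (n + 2)


def fit_target_model(
    dataset: InteractionDataset,
    target_id: str,
    exclude_ligand: str | None = None,
    *,
    alpha: float = 1.0,
    level: int = 2,
) -> MNABayesClassifier:
    """Fit one target's classifier from its indexed ligands.

    ``exclude_ligand`` is omitted entirely from the counts (leave-one-out);
    excluding a ligand that is not among the target's indexed ligands yields
    the same model as no exclusion.
    """
    if target_id not in dataset.proteins:
        raise KeyError(f"unknown target {target_id!r}")
    prior_a, prior_i = _global_priors(dataset)
    X: list[frozenset[str]] = []
    y: list[int] = []
    for lig_id, label in dataset.indexed_ligands(target_id):
        if lig_id == exclude_ligand:
            continue
        X.append(dataset.ligands[lig_id].descriptors(level))
        y.append(label)
    model = MNABayesClassifier(
        alpha=alpha, level=level, prior_active=prior_a, prior_inactive=prior_i
    )
    return model.fit(X, y)


def predict_pa_pi(model: MNABayesClassifier, descriptors) -> PaPiEstimate:
    """(Pa, Pi) of a single compound under a fitted per-target model."""
    pa, pi = model.predict_pa_pi([descriptors])[0]
    return PaPiEstimate(float(pa), float(pi))


def model_to_json(models: dict[str, MNABayesClassifier]) -> str:
    """Serialize per-target classifiers (descriptor count tables) to JSON."""
    payload = {
        target: {
            "alpha": m.alpha,
            "level": m.level,
            "prior_active": m.prior_active,
            "prior_inactive": m.prior_inactive,
            "n_active": m.n_active_,
            "n_inactive": m.n_inactive_,
            "counts": {d: list(c) for d, c in sorted(m.counts_.items())},
        }
        for target, m in sorted(models.items())
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def model_from_json(text: str) -> dict[str, MNABayesClassifier]:
    payload = json.loads(text)
    models: dict[str, MNABayesClassifier] = {}
    for target, blob in payload.items():
        m = MNABayesClassifier(
            alpha=blob["alpha"],
            level=blob["level"],
            prior_active=blob["prior_active"],
            prior_inactive=blob["prior_inactive"],
        )
        m.counts_ = {d: (int(ca), int(ci)) for d, (ca, ci) in blob["counts"].items()}
        m.n_active_ = int(blob["n_active"])
        m.n_inactive_ = int(blob["n_inactive"])
        m.degenerate_ = m.n_active_ == 0 or m.n_inactive_ == 0
        m.classes_ = np.array([0, 1])
        models[target] = m
    return models
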