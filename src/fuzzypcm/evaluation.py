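"""Leave-one-out evaluation scenarios and ROC/AUC accuracy estimation.

Three prediction tasks are simulated on a curated dataset:

1. *New ligand* — each ligand is alternately removed from the training set
   and scored against every training target with an index by the per-target
   naive-Bayes Pa - Pi.
2. *New target* — each protein is alternately removed from the training
   sequences and every ligand indexed on it is scored with the
   segment-similarity estimate B under BINARY belonging coefficients.
3. *Both new* — each (protein, ligand) indexed pair is double-held-out: the
   protein leaves the training sequences and the ligand leaves every
   naive-Bayes fit; B is computed with FUZZY coefficients (Pa_k, Pi_k).

All scored pairs of a dataset are pooled into one ROC (one AUC per
dataset); per-ligand macro-averaging is available behind a flag.  Labels
are always the curated binary indices, whichever coefficients produced the
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .bayes import _global_priors, pa_pi_from_counts
from .curation import InteractionDataset
from .model import binary_coefficients, interaction_estimate
from .scoring import pairwise_positional_scores

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "roc_auc",
    "scenario1_new_ligand",
    "scenario2_new_target",
    "scenario3_both_new",
]


@dataclass
class ROCResult:
    """Pooled ROC over scored (protein, ligand) pairs.

    ``auc`` is the Mann-Whitney statistic of the score ranking (ties count
    half), equal to the trapezoidal area under the TPR/FPR curve.
    """

    auc: float
    n_pos: int
    n_neg: int
    scores: pd.DataFrame  # columns: protein_id, ligand_id, score, label

    @property
    def n_pairs(self) -> int:
        return self.n_pos + self.n_neg


def roc_auc(scores: pd.DataFrame | list) -> ROCResult:
    """ROC AUC of scored pairs (midrank tie handling).

    ``scores`` is a DataFrame with columns protein_id, ligand_id, score,
    label — or a list of such tuples.  Requires both classes present.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(
            scores, columns=["protein_id", "ligand_id", "score", "label"]
        )
    if scores.empty:
        raise ValueError("no scored pairs")
    labels = scores["label"].to_numpy()
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("cannot compute ROC: no positive-label pairs")
    if n_neg == 0:
        raise ValueError("cannot compute ROC: no negative-label pairs")
    auc = float(roc_auc_score(labels, scores["score"].to_numpy()))
    return ROCResult(auc=auc, n_pos=n_pos, n_neg=n_neg, scores=scores)


def _macro_average(scores: pd.DataFrame) -> float:
    """Per-ligand macro-averaged AUC over ligands carrying both classes."""
    aucs = []
    for _, group in scores.groupby("ligand_id"):
        labels = group["label"].to_numpy()
        if 0 < labels.sum() < len(labels):
            aucs.append(roc_auc_score(labels, group["score"].to_numpy()))
    if not aucs:
        raise ValueError("no ligand has both classes; macro-averaging undefined")
    return float(np.mean(aucs))


def _loo_count_getter(counts: dict, exclude_descriptors: frozenset, y_excluded: int | None):
    """Count lookup with one ligand's contribution decremented.

    Identical to refitting without the ligand: counts are additive, and the
    excluded ligand touches exactly its own descriptors.
    """
    if y_excluded is None:
        return counts.get

    def get(d):
        cnt = counts.get(d)
        if cnt is None:
            return None
        if d in exclude_descriptors:
            ca, ci = cnt
            if y_excluded == 1:
                ca -= 1
            else:
                ci -= 1
            return (ca, ci)
        return cnt

    return get


def _target_counts(dataset: InteractionDataset, level: int):
    """Per-target descriptor count tables over all indexed ligands."""
    tables: dict[str, tuple[dict, int, int]] = {}
    for pid in sorted(dataset.proteins):
        counts: dict[str, list[int]] = {}
        n_a = n_i = 0
        for lig_id, label in dataset.indexed_ligands(pid):
            if label == 1:
                n_a += 1
            else:
                n_i += 1
            col = 0 if label == 1 else 1
            for d in dataset.ligands[lig_id].descriptors(level):
                counts.setdefault(d, [0, 0])[col] += 1
        tables[pid] = ({d: (ca, ci) for d, (ca, ci) in counts.items()}, n_a, n_i)
    return tables


def scenario1_new_ligand(
    dataset: InteractionDataset,
    *,
    alpha: float = 1.0,
    level: int = 2,
    ranking: str = "pa-pi",
    pooled: bool = True,
) -> ROCResult:
    """First scenario: each ligand held out, scored against its indexed
    targets by the leave-one-out naive-Bayes Pa - Pi (or Pa alone)."""
    if dataset.n_ligands < 2:
        raise ValueError("cannot leave one ligand out of a single-ligand dataset")
    if ranking not in ("pa-pi", "pa"):
        raise ValueError(f"ranking must be 'pa-pi' or 'pa', got {ranking!r}")
    prior_a, prior_i = _global_priors(dataset)
    tables = _target_counts(dataset, level)

    rows = []
    for pid in sorted(dataset.proteins):
        counts, n_a, n_i = tables[pid]
        for lig_id, label in dataset.indexed_ligands(pid):
            descriptors = dataset.ligands[lig_id].descriptors(level)
            pa, pi = pa_pi_from_counts(
                descriptors,
                _loo_count_getter(counts, descriptors, label),
                n_a - (label == 1),
                n_i - (label == 0),
                alpha,
                prior_a,
                prior_i,
            )
            score = pa - pi if ranking == "pa-pi" else pa
            rows.append((pid, lig_id, score, label))
    result = roc_auc(rows)
    if not pooled:
        result.auc = _macro_average(result.scores)
    return result


def scenario2_new_target(
    dataset: InteractionDataset,
    *,
    frame: int = 7,
    score_cache: dict | None = None,
    pooled: bool = True,
) -> ROCResult:
    """Second scenario: each protein held out of the training sequences;
    its indexed ligands scored by B with BINARY coefficients."""
    if dataset.n_proteins < 2:
        raise ValueError("cannot leave one protein out of a single-protein dataset")
    if score_cache is None:
        score_cache = pairwise_positional_scores(dataset.proteins, frame)

    rows = []
    for pid in sorted(dataset.proteins):
        train_ids = [k for k in sorted(dataset.proteins) if k != pid]
        scores = np.column_stack([score_cache[(pid, k)] for k in train_ids])
        for lig_id, label in dataset.indexed_ligands(pid):
            a, b = binary_coefficients(dataset, lig_id, train_ids)
            if a.sum() == 0:
                logger.warning(
                    "skipping pair (%s, %s): removing %s empties the ligand's interactor set",
                    pid, lig_id, pid,
                )
                continue
            result = interaction_estimate(scores, a, b)
            rows.append((pid, lig_id, result.b, label))
    result = roc_auc(rows)
    if not pooled:
        result.auc = _macro_average(result.scores)
    return result


def scenario3_both_new(
    dataset: InteractionDataset,
    *,
    frame: int = 7,
    alpha: float = 1.0,
    level: int = 2,
    score_cache: dict | None = None,
    pooled: bool = True,
) -> ROCResult:
    """Third scenario: double hold-out per indexed pair — the protein leaves
    the training sequences and the ligand leaves every per-target Bayes fit;
    B computed with FUZZY coefficients (Pa_k, Pi_k).  ROC labels remain the
    curated binary indices."""
    if dataset.n_proteins < 2 or dataset.n_ligands < 2:
        raise ValueError("double hold-out needs at least two proteins and two ligands")
    if score_cache is None:
        score_cache = pairwise_positional_scores(dataset.proteins, frame)
    prior_a, prior_i = _global_priors(dataset)
    tables = _target_counts(dataset, level)
    all_targets = sorted(dataset.proteins)
    all_ligands = sorted(dataset.ligands)

    # (target k, ligand C) -> (Pa, Pi) with C excluded from k's fit
    papi: dict[tuple[str, str], tuple[float, float]] = {}
    for k in all_targets:
        counts, n_a, n_i = tables[k]
        for lig_id in all_ligands:
            label = dataset.indices.get((k, lig_id))
            descriptors = dataset.ligands[lig_id].descriptors(level)
            papi[(k, lig_id)] = pa_pi_from_counts(
                descriptors,
                _loo_count_getter(counts, descriptors, label),
                n_a - (label == 1),
                n_i - (label == 0),
                alpha,
                prior_a,
                prior_i,
            )

    rows = []
    for pid in all_targets:
        train_ids = [k for k in all_targets if k != pid]
        scores = np.column_stack([score_cache[(pid, k)] for k in train_ids])
        for lig_id, label in dataset.indexed_ligands(pid):
            a = np.array([papi[(k, lig_id)][0] for k in train_ids])
            b = np.array([papi[(k, lig_id)][1] for k in train_ids])
            result = interaction_estimate(scores, a, b)
            rows.append((pid, lig_id, result.b, label))
    result = roc_auc(rows)
    if not pooled:
        result.auc = _macro_average(result.scores)
    return result
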