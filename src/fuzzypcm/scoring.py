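"""Segment-based positional similarity scores between protein sequences.

A test sequence Q is compared with a training sequence K by superimposing
ungapped segments ("frames") of fixed length F at every shift.  The segment
score for a frame starting at position i of Q under shift h is

    R_ih = sum_{j=i}^{i+F-1} sim(q_j, k_{j+h}),

with sim the residue identity metric here (1 for equal standard residues,
0 otherwise).  The positional score of position p against K is the maximum
R over all frames containing p at all shifts:

    S_pk = max_{h, i: p-F < i <= p} R_ih,

i.e. the best full-length-F window covering p at any ungapped offset.
Frames must lie fully inside both sequences (exactly F aligned pairs; no
overhang/padding convention).  Coordinates in the public interface are
1-based inclusive; the vectorized internals are 0-based.

The production path builds the m x n residue match matrix, accumulates
F-diagonal window sums, and reduces with sliding maxima — it matches the
naive triple loop over (p, i, h) exactly (asserted property-wise in the
test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "segment_score",
    "positional_scores",
    "score_matrix",
    "pairwise_positional_scores",
]

#: The 20 standard amino acids; ambiguity codes (B, Z, X, ...) never match,
#: even to themselves.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_RESIDUE_CODE = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}


def _encode(seq: str, offset: int = 0) -> np.ndarray:
    """Integer-encode a sequence; non-standard residues get unique negative
    codes so they compare unequal to everything, themselves included."""
    return np.array(
        [_RESIDUE_CODE.get(aa, -(pos + 1 + offset)) for pos, aa in enumerate(seq.upper())],
        dtype=np.int64,
    )


def _match_matrix(q: str, k: str) -> np.ndarray:
    qa = _encode(q)
    ka = _encode(k, offset=len(q))  # keep non-standard codes disjoint across sequences
    return (qa[:, None] == ka[None, :]).astype(np.float64)


def _window_sums(match: np.ndarray, frame: int) -> np.ndarray:
    """W[i, j] = number of matches over the F-diagonal starting at (i, j)."""
    m, n = match.shape
    out = np.zeros((m - frame + 1, n - frame + 1))
    for t in range(frame):
        out += match[t : t + m - frame + 1, t : t + n - frame + 1]
    return out


def _covering_max(window_best: np.ndarray, frame: int, m: int) -> np.ndarray:
    """S_p = max over frame starts i in (p-F, p] of window_best[i]."""
    padded = np.concatenate(
        [np.full(frame - 1, -np.inf), window_best, np.full(m - len(window_best), -np.inf)]
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, frame)
    return windows.max(axis=1)


def _check_frame(q: str, k: str, frame: int) -> None:
    if frame < 1:
        raise ValueError(f"frame must be >= 1, got {frame}")
    short = min(len(q), len(k))
    if short < frame:
        raise ValueError(
            f"frame {frame} exceeds a sequence length ({short}); use a smaller frame"
        )


def segment_score(q: str, k: str, i: int, h: int, frame: int) -> float:
    """Segment score R_ih for the frame of Q starting at 1-based position i
    aligned against K under shift h.

    The frame must lie fully inside both sequences: ``1 <= i`` and
    ``i + F - 1 <= |Q|`` on the test side, ``1 <= i + h`` and
    ``i + F - 1 + h <= |K|`` on the training side.
    """
    _check_frame(q, k, frame)
    if not (1 <= i and i + frame - 1 <= len(q)):
        raise ValueError(f"frame start i={i} (length {frame}) overhangs Q of length {len(q)}")
    if not (1 <= i + h and i + frame - 1 + h <= len(k)):
        raise ValueError(f"shift h={h} places the frame outside K of length {len(k)}")
    q = q.upper()
    k = k.upper()
    return float(
        sum(
            1.0
            for j in range(i - 1, i - 1 + frame)
            if q[j] in _RESIDUE_CODE and q[j] == k[j + h]
        )
    )


def positional_scores(q: str, k: str, frame: int) -> np.ndarray:
    """Vector of positional scores S_p of test sequence Q against training
    sequence K, for p = 1..|Q| (returned 0-indexed)."""
    _check_frame(q, k, frame)
    match = _match_matrix(q, k)
    w = _window_sums(match, frame)
    return _covering_max(w.max(axis=1), frame, len(q))


def score_matrix(q: str, training: dict[str, str], frame: int) -> tuple[np.ndarray, list[str]]:
    """Stack positional scores of Q against every training sequence.

    Returns an ``(|Q|, N)`` matrix and the training identifiers defining the
    column order (sorted for determinism).
    """
    ids = sorted(training)
    if not ids:
        raise ValueError("training sequence set is empty")
    cols = [positional_scores(q, training[k], frame) for k in ids]
    return np.column_stack(cols), ids


def pairwise_positional_scores(
    sequences: dict[str, str], frame: int
) -> dict[tuple[str, str], np.ndarray]:
    """All-vs-all positional score vectors, computed once per unordered pair.

    ``result[(a, b)]`` holds S_p of sequence ``a`` (test role) against ``b``
    (training role).  One match matrix serves both orientations: maximizing
    window sums over training starts gives one direction, over test starts
    the other.
    """
    ids = sorted(sequences)
    for sid in ids:
        if len(sequences[sid]) < frame:
            raise ValueError(
                f"frame {frame} exceeds the length of sequence {sid!r} "
                f"({len(sequences[sid])}); use a smaller frame"
            )
    cache: dict[tuple[str, str], np.ndarray] = {}
    for ai, a in enumerate(ids):
        cache[(a, a)] = _covering_max(
            _window_sums(_match_matrix(sequences[a], sequences[a]), frame).max(axis=1),
            frame,
            len(sequences[a]),
        )
        for b in ids[ai + 1 :]:
            match = _match_matrix(sequences[a], sequences[b])
            w = _window_sums(match, frame)
            cache[(a, b)] = _covering_max(w.max(axis=1), frame, len(sequences[a]))
            cache[(b, a)] = _covering_max(w.max(axis=0), frame, len(sequences[b]))
    return cache
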