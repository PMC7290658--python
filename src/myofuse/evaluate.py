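"""Scoring detected nuclei against ground truth."""

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchResult", "match_points"]


@dataclass(frozen=True)
class MatchResult:
    n_true: int
    n_detected: int
    n_matched: int
    pairs: list  # (true_index, detected_index, distance)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0


def match_points(truth: np.ndarray, detected: np.ndarray, max_dist: float) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth points.

    Candidate pairs within ``max_dist`` are matched in order of increasing
    distance; each point participates in at most one pair.
    """
    t = np.asarray(truth, dtype=float).reshape(-1, 2)
    d = np.asarray(detected, dtype=float).reshape(-1, 2)
    if len(t) == 0 or len(d) == 0:
        return MatchResult(len(t), len(d), 0, [])
    dist = np.hypot(t[:, None, 0] - d[None, :, 0], t[:, None, 1] - d[None, :, 1])
    ti, di = np.nonzero(dist <= max_dist)
    order = np.argsort(dist[ti, di], kind="stable")
    used_t = np.zeros(len(t), dtype=bool)
    used_d = np.zeros(len(d), dtype=bool)
    pairs = []
    for k in order:
        i, j = ti[k], di[k]
        if used_t[i] or used_d[j]:
            continue
        used_t[i] = used_d[j] = True
        pairs.append((int(i), int(j), float(dist[i, j])))
    return MatchResult(len(t), len(d), len(pairs), pairs)
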