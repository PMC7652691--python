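"""Partition agreement between training and replication networks.

Cluster structure is compared on the comorbidity nodes only (the patient
populations of the two years differ, so a patient-node comparison is
undefined).  The headline statistic is the plain Rand index — the
fraction of element pairs on which two partitions agree (co-clustered in
both or separated in both) — with a permutation significance test whose
null shuffles one partition's labels across elements while preserving its
cluster sizes.  The adjusted Rand index is available as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import DataValidationError

__all__ = ["RIResult", "rand_index", "adjusted_rand_index", "ri_significance"]


@dataclass
class RIResult:
    ri: float
    random_mean: float
    random_sd: float
    n_permutations: int
    p_value: float


def _aligned_labels(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    """Two integer label vectors over the same element set."""
    if isinstance(labels_a, dict) or isinstance(labels_b, dict):
        if not (isinstance(labels_a, dict) and isinstance(labels_b, dict)):
            raise DataValidationError("mix of mapping and sequence labels")
        if set(labels_a) != set(labels_b):
            raise DataValidationError("partitions cover different element sets")
        keys = sorted(labels_a, key=str)
        la = [labels_a[k] for k in keys]
        lb = [labels_b[k] for k in keys]
    else:
        la, lb = list(labels_a), list(labels_b)
        if len(la) != len(lb):
            raise DataValidationError("label vectors differ in length")
    if len(la) < 2:
        raise DataValidationError("need >= 2 elements")
    _, ia = np.unique(np.asarray(la, dtype=object), return_inverse=True)
    _, ib = np.unique(np.asarray(lb, dtype=object), return_inverse=True)
    return ia, ib


def _pair_counts(ia: np.ndarray, ib: np.ndarray):
    """Contingency-based pair bookkeeping shared by RI and ARI."""
    n = ia.size
    cont = np.zeros((ia.max() + 1, ib.max() + 1), dtype=np.int64)
    np.add.at(cont, (ia, ib), 1)
    sum_ij = sum(comb(int(v), 2) for v in cont.ravel())
    sum_a = sum(comb(int(v), 2) for v in cont.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in cont.sum(axis=0))
    total = comb(n, 2)
    return sum_ij, sum_a, sum_b, total


def rand_index(labels_a, labels_b) -> float:
    """Fraction of element pairs on which the two partitions agree.

    Accepts two equal-length label sequences or two node->label mappings
    over the same element set; label values themselves are arbitrary.
    """
    ia, ib = _aligned_labels(labels_a, labels_b)
    sum_ij, sum_a, sum_b, total = _pair_counts(ia, ib)
    # agree = both-together + both-apart
    return (total + 2 * sum_ij - sum_a - sum_b) / total


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index (Hubert-Arabie)."""
    ia, ib = _aligned_labels(labels_a, labels_b)
    sum_ij, sum_a, sum_b, total = _pair_counts(ia, ib)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def ri_significance(
    labels_a,
    labels_b,
    n_permutations: int = 1000,
    seed: int = 0,
    null: str = "shuffle",
) -> RIResult:
    """Permutation test of the Rand index.

    ``null="shuffle"`` (default) permutes which element carries which
    label in the second partition, preserving its cluster sizes;
    ``null="random_partition"`` draws the second partition's labels
    uniformly at random (same number of clusters) as a sensitivity
    alternative.  p = (1 + #{RI_perm >= RI_obs}) / (R + 1).
    """
    if n_permutations < 1:
        raise DataValidationError("need >= 1 permutation")
    ia, ib = _aligned_labels(labels_a, labels_b)
    ri_obs = rand_index(ia, ib)
    rng = np.random.default_rng(seed)
    ris = np.empty(n_permutations)
    n_clusters_b = int(ib.max()) + 1
    for r in range(n_permutations):
        if null == "shuffle":
            perm = rng.permutation(ib)
        elif null == "random_partition":
            perm = rng.integers(0, n_clusters_b, size=ib.size)
        else:
            raise DataValidationError(f"unknown null {null!r}")
        ris[r] = rand_index(ia, perm)
    p = (1 + int((ris >= ri_obs - 1e-12).sum())) / (n_permutations + 1)
    return RIResult(
        ri_obs, float(ris.mean()),
        float(ris.std(ddof=1)) if n_permutations > 1 else 0.0,
        n_permutations, p,
    )
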