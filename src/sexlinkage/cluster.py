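"""Categorical genotype clustering shared by the WGS and association scans.

Individuals are compared over genotype vectors (homozygous reference,
heterozygous, homozygous alternative, missing). For all-categorical data
Gower's dissimilarity reduces to the simple mismatch fraction over positions
at which both individuals have a call. The 2-cluster cut used to test whether
individuals group by sex comes from divisive hierarchical clustering (DIANA):
the object with the greatest average dissimilarity seeds a splinter group,
which then attracts every object closer on average to the splinter than to
the remainder.
"""

from __future__ import annotations

import numpy as np

from .io_prep import GT_MISSING


def gower_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise Gower (mismatch-fraction) distances between individuals.

    ``genotypes`` is (n_sites, n_individuals) with code -1 for missing.
    Pairs with no jointly called site get distance 1.
    """
    g = np.asarray(genotypes)
    n = g.shape[1]
    d = np.zeros((n, n))
    called = g != GT_MISSING
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1 :]
        mism = (g[:, i][:, None] != g[:, i + 1 :]) & both
        denom = both.sum(axis=0)
        with np.errstate(invalid="ignore"):
            row = np.where(denom > 0, mism.sum(axis=0) / np.maximum(denom, 1), 1.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def diana_two_clusters(d: np.ndarray) -> np.ndarray:
    """First divisive split of the DIANA algorithm.

    Returns a boolean array: True for members of the splinter group. With
    fewer than 2 objects, or all-zero dissimilarities, no split is made
    (all False).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2 or np.allclose(d, 0):
        return np.zeros(n, dtype=bool)
    in_splinter = np.zeros(n, dtype=bool)
    avg_all = d.sum(axis=1) / (n - 1)
    in_splinter[int(np.argmax(avg_all))] = True
    while True:
        rest = ~in_splinter
        n_rest = rest.sum()
        if n_rest <= 1:
            break
        idx_rest = np.flatnonzero(rest)
        # average distance of each remaining object to remainder vs splinter
        to_rest = d[np.ix_(idx_rest, idx_rest)].sum(axis=1) / (n_rest - 1)
        to_spl = d[np.ix_(idx_rest, np.flatnonzero(in_splinter))].mean(axis=1)
        gain = to_rest - to_spl
        best = int(np.argmax(gain))
        if gain[best] <= 0:
            break
        in_splinter[idx_rest[best]] = True
    return in_splinter


def splits_by_sex(
    labels_splinter: np.ndarray, sexes: list[str], individuals_idx: list[int]
) -> bool:
    """Whether a set of individuals separates by sex at the 2-cluster cut.

    True iff the individuals at ``individuals_idx`` fall in exactly two
    groups that coincide with their sexes (both sexes present).
    """
    groups = {}
    for idx in individuals_idx:
        groups.setdefault(bool(labels_splinter[idx]), set()).add(sexes[idx])
    if len(groups) != 2:
        return False
    g1, g2 = groups.values()
    return len(g1) == 1 and len(g2) == 1 and g1 != g2
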