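"""Permutation distribution clustering of ontogeny profiles.

A series is embedded in windows of m consecutive (delay-t) values; each
window is reduced to its ordinal pattern (the permutation that sorts
it), and the series is summarised by the frequency distribution over the
m! patterns.  Because ranks ignore scale and any monotone transform,
this codebook compares the *trend* of profiles, not their magnitudes —
which is why profiles are first standardised to a common length.
Distributions are compared with the symmetric alpha divergence (at
alpha = 0.5, four times one minus the Bhattacharyya coefficient), summed
over the selected profile variables, and shells are grouped by
single-linkage hierarchical clustering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .profiles import PROFILE_VARIABLES, OntogenyProfileMatrix


@dataclass
class PermutationDistribution:
    """Frequencies of the m! ordinal patterns of an embedded series."""

    m: int
    t: int
    frequencies: np.ndarray
    n_windows: int

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != math.factorial(self.m):
            raise ValueError("frequency vector must have length m!")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise divergences between shells' profile codebooks."""

    shell_ids: list[str]
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.shell_ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape must match shell count")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.shell_ids, columns=self.shell_ids)


@dataclass
class Dendrogram:
    """Single-linkage merge history with Newick serialisation.

    ``merges`` is the scipy linkage matrix: each row (a, b, height, size)
    merges clusters a and b at the given height.
    """

    shell_ids: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights.

        A leaf's branch length is half the height of the merge that
        absorbs it (heights are cophenetic distances between clusters);
        internal branch lengths are half the height difference between
        consecutive merges.
        """
        n = len(self.shell_ids)
        nodes = {i: (self.shell_ids[i], 0.0) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            la, ha = nodes.pop(int(a))
            lb, hb = nodes.pop(int(b))
            half = h / 2.0
            nodes[n + k] = (f"({la}:{half - ha:.6g},{lb}:{half - hb:.6g})", half)
        (label, _), = nodes.values()
        return label + ";"


def _pattern_index(m: int):
    """Map from ordinal-pattern tuple to index in the m!-vector, in
    lexicographic pattern order."""
    return {p: i for i, p in enumerate(itertools.permutations(range(m)))}


def ordinal_pattern(window: np.ndarray) -> tuple[int, ...]:
    """Rank pattern of a window; ties rank the earlier index lower.

    Returns the permutation of ranks, e.g. (0, 2, 1) for a window whose
    first value is smallest and second value largest.
    """
    order = np.argsort(window, kind="stable")  # stable => earlier index first on ties
    ranks = np.empty(len(window), dtype=int)
    ranks[order] = np.arange(len(window))
    return tuple(int(r) for r in ranks)


def permutation_distribution(
    series, m: int = 5, t: int = 1
) -> PermutationDistribution:
    """Ordinal-pattern frequency distribution of a series.

    Embeds windows (x_i, x_{i+t}, ..., x_{i+(m-1)t}) — there are
    n - (m-1)t of them — and counts each window's rank pattern.
    """
    x = np.asarray(series, dtype=float).ravel()
    min_len = (m - 1) * t + 1
    if len(x) < min_len:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, t={t}; "
            f"need at least {min_len}"
        )
    idx = _pattern_index(m)
    counts = np.zeros(math.factorial(m))
    n_windows = len(x) - (m - 1) * t
    for i in range(n_windows):
        counts[idx[ordinal_pattern(x[i : i + (m - 1) * t + 1 : t])]] += 1
    return PermutationDistribution(
        m=m, t=t, frequencies=counts / n_windows, n_windows=n_windows
    )


def symmetric_alpha_divergence(
    p: PermutationDistribution, q: PermutationDistribution, alpha: float = 0.5
) -> float:
    """Symmetric alpha divergence between two pattern distributions.

    At alpha = 0.5 this is 2 * sum_i (sqrt(p_i) - sqrt(q_i))^2, i.e.
    4 * (1 - Bhattacharyya coefficient): symmetric, zero iff p == q,
    finite with empty cells, and at most 4 (disjoint supports).  Other
    alpha values use the symmetrised form
    (D_alpha(p||q) + D_alpha(q||p)) / 2 with
    D_alpha(p||q) = (1/(alpha(1-alpha))) * sum_i
        [alpha p_i + (1-alpha) q_i - p_i^alpha q_i^(1-alpha)],
    which reduces to the closed form as alpha -> 0.5.
    """
    if (p.m, p.t) != (q.m, q.t):
        raise ValueError(
            f"mismatched embeddings: (m={p.m}, t={p.t}) vs (m={q.m}, t={q.t})"
        )
    fp, fq = p.frequencies, q.frequencies
    if alpha == 0.5:
        return float(2.0 * ((np.sqrt(fp) - np.sqrt(fq)) ** 2).sum())
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    c = 1.0 / (alpha * (1.0 - alpha))

    def one_sided(u, v):
        return c * (alpha * u + (1 - alpha) * v - u**alpha * v ** (1 - alpha)).sum()

    return float(0.5 * (one_sided(fp, fq) + one_sided(fq, fp)))


def pdc_matrix(
    profile_set: list[OntogenyProfileMatrix],
    variables=PROFILE_VARIABLES,
    m: int = 5,
    t: int = 1,
    alpha: float = 0.5,
    combine: str = "sum",
) -> DissimilarityMatrix:
    """Pairwise PDC dissimilarities over the selected profile variables.

    Each shell contributes one permutation distribution per variable;
    the entry D[i, j] combines the per-variable divergences by ``sum``
    (default) or ``mean``.
    """
    if len(profile_set) < 2:
        raise ValueError("need at least 2 shells")
    lengths = {len(p) for p in profile_set}
    if len(lengths) != 1:
        raise ValueError(f"profiles have inconsistent lengths: {sorted(lengths)}")
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    variables = list(variables)
    dists = [
        [permutation_distribution(p.series(v), m, t) for v in variables]
        for p in profile_set
    ]
    n = len(profile_set)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            per_var = [
                symmetric_alpha_divergence(a, b, alpha)
                for a, b in zip(dists[i], dists[j])
            ]
            D[i, j] = D[j, i] = (
                np.sum(per_var) if combine == "sum" else np.mean(per_var)
            )
    return DissimilarityMatrix(shell_ids=[p.shell_id for p in profile_set], D=D)


def single_linkage(dm: DissimilarityMatrix) -> Dendrogram:
    """Single-linkage agglomeration of the dissimilarity matrix."""
    if len(dm.shell_ids) < 2:
        raise ValueError("need at least 2 shells to cluster")
    merges = linkage(squareform(dm.D, checks=False), method="single")
    return Dendrogram(shell_ids=list(dm.shell_ids), merges=merges)
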