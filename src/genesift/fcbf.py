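"""Stage 1 — the Fast Correlation-Based Filter (FCBF).

Genes are ranked by symmetrical uncertainty with the class label, genes at or
below a relevance threshold ``delta`` are dropped, and redundancy is removed
by the predominant-feature rule: walking the ranking from the top, a
lower-ranked gene g_j is eliminated whenever some kept gene g_i satisfies
SU(g_j, g_i) >= SU(g_j, C).  Pairwise SU is computed lazily during the sweep
(only against currently-kept genes), never as a full gene-by-gene matrix, so
the filter stays cheap on matrices with hundreds to thousands of genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .infotheory import DiscretizedMatrix, discretize, symmetrical_uncertainty

__all__ = ["SURanking", "CandidateSet", "rank_by_su", "fcbf_select", "FCBFSelector"]


@dataclass
class SURanking:
    """Genes with SU-to-class strictly above ``delta``, sorted descending.

    Ties in SU are broken by ascending gene identifier for a stable,
    reproducible ordering.
    """

    entries: list  # of (gene_id, su_with_class)
    delta: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list:
        return [g for g, _ in self.entries]


@dataclass
class CandidateSet:
    """Stage-1 output: predominant (non-redundant) genes in ranking order."""

    genes: list
    su_with_class: dict

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_su(data: DiscretizedMatrix, labels, delta: float = 0.0) -> SURanking:
    """Rank genes by SU with the class, keeping those with SU > delta."""
    y = np.asarray(labels)
    if y.shape[0] != data.codes.shape[0]:
        raise ValueError("labels length does not match sample count")
    if np.unique(y).size < 2:
        raise ValueError(
            "class entropy is zero; SU with class undefined as a ranking"
        )
    if delta < 0:
        raise ValueError("delta must be >= 0")
    scored = []
    for j, gene in enumerate(data.gene_ids):
        su = symmetrical_uncertainty(data.codes[:, j], y)
        if su > delta:
            scored.append((gene, su))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SURanking(entries=scored, delta=float(delta))


def fcbf_select(ranking: SURanking, data: DiscretizedMatrix) -> CandidateSet:
    """Predominant-feature sweep over an SU ranking.

    Walks the ranking from the highest SU(g, C); each gene kept removes every
    surviving lower-ranked gene g_j with SU(g_j, g_kept) >= SU(g_j, C).
    Output preserves ranking order and is deterministic.
    """
    col_of = {g: j for j, g in enumerate(data.gene_ids)}
    for gene, _ in ranking.entries:
        if gene not in col_of:
            raise ValueError(f"gene {gene!r} in ranking but missing from data")
    entries = ranking.entries
    alive = [True] * len(entries)
    kept: list = []
    su_class: dict = {}
    for i, (g_i, su_i) in enumerate(entries):
        if not alive[i]:
            continue
        kept.append(g_i)
        su_class[g_i] = su_i
        col_i = data.codes[:, col_of[g_i]]
        for j in range(i + 1, len(entries)):
            if not alive[j]:
                continue
            g_j, su_j = entries[j]
            if symmetrical_uncertainty(data.codes[:, col_of[g_j]], col_i) >= su_j:
                alive[j] = False
    return CandidateSet(genes=kept, su_with_class=su_class)


class FCBFSelector(SelectorMixin, BaseEstimator):
    """Fast Correlation-Based Filter as a scikit-learn feature selector.

    Discretizes each gene, ranks genes by symmetrical uncertainty with the
    binary class label, drops genes with SU <= ``delta``, and removes
    redundant genes via the predominant-feature rule.

    Parameters
    ----------
    delta : relevance threshold; a gene is a candidate only if its SU with
        the class strictly exceeds it.  Default 0 keeps any gene with
        positive SU.
    discretization : ``"mdl"`` (supervised Fayyad–Irani, default),
        ``"equal_frequency"`` or ``"equal_width"``.
    n_bins : bin count for the unsupervised discretizers.

    Attributes
    ----------
    ranking_ : SURanking over the input genes.
    candidates_ : CandidateSet after redundancy elimination.
    support_ : boolean mask over input columns.
    selected_indices_ : column indices of the candidates, in ranking order.
    """

    def __init__(self, delta: float = 0.0, discretization: str = "mdl", n_bins: int = 10):
        self.delta = delta
        self.discretization = discretization
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        gene_ids = [f"g{j:05d}" for j in range(X.shape[1])]
        disc = discretize(
            X, labels=y, method=self.discretization, n_bins=self.n_bins, gene_ids=gene_ids
        )
        self.ranking_ = rank_by_su(disc, y, delta=self.delta)
        self.candidates_ = fcbf_select(self.ranking_, disc)
        index = {g: j for j, g in enumerate(gene_ids)}
        self.selected_indices_ = np.array(
            [index[g] for g in self.candidates_.genes], dtype=int
        )
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.selected_indices_] = True
        self.support_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
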