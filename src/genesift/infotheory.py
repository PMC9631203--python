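"""Information-theoretic primitives for correlation-based gene filtering.

Shannon entropy, conditional entropy and symmetrical uncertainty (SU) over
discrete vectors, plus the discretizers that turn a continuous expression
matrix into the integer codes those quantities need.  Everything here uses
empirical plug-in probabilities with no smoothing, and log base 2, so
entropies are reported in bits.

Symmetrical uncertainty,

    SU(X, Y) = 2 [H(X) - H(X|Y)] / (H(X) + H(Y)),

is a normalised mutual information in [0, 1]: 1 when either variable
determines the other, 0 when they are empirically independent.  It is the
relevance/redundancy measure of the fast correlation-based filter (FCBF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedMatrix",
    "entropy",
    "conditional_entropy",
    "symmetrical_uncertainty",
    "discretize",
]

_LOG2 = np.log(2.0)


def _as_codes(x) -> np.ndarray:
    """Map an arbitrary discrete vector to contiguous integer codes."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("entropy requires a non-empty vector")
    _, codes = np.unique(x, return_inverse=True)
    return codes


def entropy(x) -> float:
    """Shannon entropy of a discrete vector, in bits.

    Empirical plug-in estimate: H(X) = -sum p_i log2 p_i with p_i the
    observed frequencies.  A constant vector has entropy 0.
    """
    codes = _as_codes(x)
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(x, y) -> float:
    """Conditional entropy H(X|Y) in bits, from the empirical joint table.

    H(X|Y) = sum_y p(y) H(X | Y = y) = H(X, Y) - H(Y); always satisfies
    0 <= H(X|Y) <= H(X).
    """
    cx = _as_codes(x)
    cy = _as_codes(y)
    if cx.size != cy.size:
        raise ValueError(
            f"length mismatch: x has {cx.size} entries, y has {cy.size}"
        )
    n_y = int(cy.max()) + 1
    joint = cx * n_y + cy
    return max(0.0, entropy(joint) - entropy(cy))


def symmetrical_uncertainty(x, y) -> float:
    """Symmetrical uncertainty SU(X, Y) = 2 [H(X) - H(X|Y)] / (H(X) + H(Y)).

    Returns a value in [0, 1]; symmetric in its arguments and invariant to
    relabeling of category codes.  When both vectors are constant the ratio
    is 0/0 and we return 0 by convention (a constant variable carries no
    information); when exactly one is constant the numerator vanishes and
    the result is 0 as well.
    """
    hx = entropy(x)
    hy = entropy(y)
    denom = hx + hy
    if denom <= 0.0:
        return 0.0
    mi = hx - conditional_entropy(x, y)
    su = 2.0 * mi / denom
    # guard tiny negative / >1 float noise
    return float(min(1.0, max(0.0, su)))


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizedMatrix:
    """Per-gene integer bin codes for a samples x genes matrix.

    Attributes
    ----------
    codes : (n_samples, n_genes) int array; each column's codes lie in
        [0, n_bins[j]).
    n_bins : (n_genes,) int array of bins per gene; a constant gene has 1.
    bin_edges : list of ascending interior cut points per gene (empty array
        for a single-bin gene).
    gene_ids : gene identifiers, one per column.
    """

    codes: np.ndarray
    n_bins: np.ndarray
    bin_edges: list = field(repr=False)
    gene_ids: list = field(default_factory=list)

    def column(self, gene) -> np.ndarray:
        """Codes for one gene, by identifier or positional index."""
        if isinstance(gene, str):
            try:
                gene = self.gene_ids.index(gene)
            except ValueError:
                raise KeyError(f"gene {gene!r} not in discretized matrix") from None
        return self.codes[:, gene]


def _validate_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("discretize requires at least 2 samples")
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing value at sample {i}, gene column {j}"
        )
    return X


def _codes_from_edges(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, values, side="right")


def _equal_frequency_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    # drop degenerate edges that would create empty leading/trailing bins
    edges = edges[(edges > values.min()) & (edges < values.max())]
    return edges


def _equal_width_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.empty(0)
    return np.linspace(lo, hi, n_bins + 1)[1:-1]


def _mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad–Irani recursive entropy minimisation with the MDL stop rule.

    A binary cut T on a segment S is accepted iff

        Gain(T; S) > log2(N - 1)/N + Delta(T; S)/N,
        Delta = log2(3^k - 2) - [k H(S) - k1 H(S1) - k2 H(S2)],

    where k, k1, k2 count the classes present in S and its two halves.
    Accepted cuts recurse into both halves; a gene with no accepted cut
    collapses to a single bin.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    n_classes = int(labels.max()) + 1
    cuts: list[float] = []

    def class_entropy(counts: np.ndarray) -> float:
        tot = counts.sum()
        p = counts[counts > 0] / tot
        return float(-(p * np.log2(p)).sum())

    def recurse(lo: int, hi: int) -> None:
        seg_v = v[lo:hi]
        seg_y = y[lo:hi]
        n = hi - lo
        if n < 2:
            return
        # candidate boundaries: between adjacent distinct values
        distinct = np.nonzero(np.diff(seg_v) > 0)[0]  # cut after index i
        if distinct.size == 0:
            return
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), seg_y] = 1.0
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        left = cum[distinct]              # counts in S1 per candidate
        right = total[None, :] - left     # counts in S2
        n1 = left.sum(axis=1)
        n2 = right.sum(axis=1)

        def h_rows(c):
            tot = c.sum(axis=1, keepdims=True)
            p = np.divide(c, tot, out=np.zeros_like(c), where=tot > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                logs = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
            return -(p * logs).sum(axis=1)

        hs = class_entropy(total)
        h1 = h_rows(left)
        h2 = h_rows(right)
        gains = hs - (n1 * h1 + n2 * h2) / n
        best = int(np.argmax(gains))
        gain = gains[best]

        k = int((total > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        delta = np.log2(3.0**k - 2.0) - (k * hs - k1 * h1[best] - k2 * h2[best])
        threshold = (np.log2(n - 1.0) + delta) / n
        if gain <= threshold:
            return
        i = distinct[best]
        cut_value = (seg_v[i] + seg_v[i + 1]) / 2.0
        cuts.append(float(cut_value))
        recurse(lo, lo + i + 1)
        recurse(lo + i + 1, hi)

    recurse(0, len(v))
    return sorted(cuts)


def discretize(
    matrix,
    labels=None,
    method: str = "mdl",
    n_bins: int = 10,
    gene_ids=None,
) -> DiscretizedMatrix:
    """Discretize each gene of a samples x genes matrix into integer codes.

    Parameters
    ----------
    matrix : real-valued (n_samples, n_genes) array-like.
    labels : binary class vector; required by (and only used by) ``mdl``.
    method : ``"mdl"`` — supervised Fayyad–Irani minimum-description-length
        binning against the labels (genes with no accepted cut collapse to a
        single bin); ``"equal_frequency"`` / ``"equal_width"`` — unsupervised
        with ``n_bins`` bins.
    n_bins : bin count for the unsupervised methods; must be >= 2 there.
    gene_ids : optional identifiers; defaults to ``g0001, g0002, ...``.

    A constant gene always maps to a single bin with all codes 0.  The
    mapping is deterministic: identical inputs and parameters give
    bit-identical codes.
    """
    X = _validate_matrix(matrix)
    n_samples, n_genes = X.shape
    if method not in ("mdl", "equal_frequency", "equal_width"):
        raise ValueError(f"unknown discretization method {method!r}")
    if method == "mdl":
        if labels is None:
            raise ValueError("mdl discretization requires labels")
        y = np.asarray(labels)
        if y.shape[0] != n_samples:
            raise ValueError(
                f"labels length {y.shape[0]} != sample count {n_samples}"
            )
        y = y.astype(int)
    else:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2 for unsupervised methods")

    if gene_ids is None:
        gene_ids = [f"g{j + 1:04d}" for j in range(n_genes)]
    gene_ids = list(gene_ids)

    codes = np.zeros((n_samples, n_genes), dtype=np.int32)
    bins = np.ones(n_genes, dtype=np.int64)
    edges_out: list[np.ndarray] = []
    for j in range(n_genes):
        col = X[:, j]
        if col.max() <= col.min():
            edges_out.append(np.empty(0))
            continue
        if method == "mdl":
            edges = np.asarray(_mdl_cut_points(col, y))
        elif method == "equal_frequency":
            edges = _equal_frequency_edges(col, n_bins)
        else:
            edges = _equal_width_edges(col, n_bins)
        edges_out.append(edges)
        if edges.size:
            codes[:, j] = _codes_from_edges(col, edges)
            bins[j] = edges.size + 1
    return DiscretizedMatrix(codes=codes, n_bins=bins, bin_edges=edges_out, gene_ids=gene_ids)
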