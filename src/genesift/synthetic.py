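"""Synthetic expression matrices with planted informative/redundant/noise genes.

Emulates the statistical shape of a differential-expression-filtered
case/control transcriptomic matrix on a log2-like scale: a small set of
class-informative genes whose class means differ by a fold-change-scale
effect, noisy near-copies of those genes (redundant, in the sense that a
correlation filter should discard them), and many label-independent noise
genes.  Class sizes default to 48 cases (label 1, "ruptured") and 40
controls (label 0, "unruptured"), and the default effect size is
log2(1.5) ~ 0.585, matching a |fold change| > 1.5 screen.

Because every gene's role is known, the generator gives the selection
pipeline an unambiguous ground truth: informative genes should be kept,
redundant copies eliminated, noise ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SyntheticSpec", "ExpressionDataset", "generate", "deg_prefilter"]


@dataclass
class ExpressionDataset:
    """Labeled samples x genes expression matrix (labels: 1 = case/ruptured)."""

    matrix: np.ndarray
    sample_ids: list
    gene_ids: list
    labels: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.gene_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class SyntheticSpec:
    """Parameters of the planted-gene generator.

    n_pos / n_neg : class sizes (default 48 case / 40 control).
    n_informative : genes with a between-class mean shift of ``effect_size``
        (log2 scale; default log2(1.5)); shift direction alternates so both
        up- and down-regulated genes are planted.
    n_redundant : noisy copies of randomly chosen informative genes,
        perturbed with sd ``redundancy_noise_sd``.
    n_noise : label-independent Normal(0, noise_sd) genes.
    """

    n_pos: int = 48
    n_neg: int = 40
    n_informative: int = 5
    n_redundant: int = 10
    n_noise: int = 600
    effect_size: float = 0.5849625007211562  # log2(1.5)
    noise_sd: float = 1.0
    redundancy_noise_sd: float = 0.1
    seed: int | None = None


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one dataset; returns (dataset, gene-role table).

    The role table has columns ``gene_id``, ``role`` (informative /
    redundant / noise) and ``parent`` (source gene for redundant copies).
    Identical seeds give bit-identical output.
    """
    if spec.n_informative + spec.n_redundant + spec.n_noise < 1:
        raise ValueError("at least one gene must be requested")
    if min(spec.n_pos, spec.n_neg) < 2:
        raise ValueError("both class sizes must be >= 2")
    if spec.n_redundant > 0 and spec.n_informative == 0:
        raise ValueError("redundant genes need at least one informative parent")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.concatenate([np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)])

    blocks, gene_ids, roles, parents = [], [], [], []
    info = np.empty((n, spec.n_informative))
    for j in range(spec.n_informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        mean = sign * spec.effect_size * labels
        info[:, j] = mean + rng.normal(0.0, spec.noise_sd, size=n)
        gene_ids.append(f"INF{j + 1:03d}")
        roles.append("informative")
        parents.append("")
    if spec.n_informative:
        blocks.append(info)

    if spec.n_redundant:
        src = rng.integers(0, spec.n_informative, size=spec.n_redundant)
        red = info[:, src] + rng.normal(0.0, spec.redundancy_noise_sd, size=(n, spec.n_redundant))
        blocks.append(red)
        for j, s in enumerate(src):
            gene_ids.append(f"RED{j + 1:03d}")
            roles.append("redundant")
            parents.append(f"INF{s + 1:03d}")

    if spec.n_noise:
        blocks.append(rng.normal(0.0, spec.noise_sd, size=(n, spec.n_noise)))
        for j in range(spec.n_noise):
            gene_ids.append(f"NSE{j + 1:04d}")
            roles.append("noise")
            parents.append("")

    matrix = np.concatenate(blocks, axis=1)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    dataset = ExpressionDataset(
        matrix=matrix, sample_ids=sample_ids, gene_ids=gene_ids, labels=labels
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "role": roles, "parent": parents})
    return dataset, truth


def deg_prefilter(
    X,
    y,
    gene_ids=None,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> list:
    """Differential-expression screen: Welch t-test p-value + fold change.

    Assumes expression on a log-like scale, so |fold change| > t translates
    to |class-mean difference| > log2(t); ``fc_threshold <= 1`` degenerates
    to requiring any non-zero difference.  Returns the identifiers (or
    column indices) of genes passing both thresholds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if gene_ids is None:
        gene_ids = list(range(X.shape[1]))
    pos = X[y == 1]
    neg = X[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    diff = np.abs(pos.mean(axis=0) - neg.mean(axis=0))
    lfc = np.log2(fc_threshold) if fc_threshold > 1.0 else 0.0
    keep = (pvals < p_threshold) & (diff > lfc)  # NaN p-values compare False
    return [g for g, k in zip(gene_ids, keep) if k]
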