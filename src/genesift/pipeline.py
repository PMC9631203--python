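"""End-to-end orchestration of the two-stage hybrid gene selection.

Wires the stages together: FCBF filtering of the full gene universe, the
PSO/MLP wrapper search over the surviving candidates, and the ten-family
cross-validated benchmark before and after selection.  Two evaluation
protocols are offered:

``paper``
    Select on the full dataset, then benchmark by k-fold CV on the same
    samples.  This replicates the common (optimistically biased) published
    procedure in which selection sees every sample before the benchmark.
``nested``
    Repeat the entire selection inside each outer CV training fold and
    score only the outer test folds — the leakage-free estimate.  Slower by
    a factor of k, and per-fold subsets may differ.

All stage RNGs are derived deterministically from one master seed, so a run
is byte-for-byte reproducible, and each stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    MODEL_NAMES,
    BenchmarkReport,
    _quiet_fit,
    benchmark_suite,
    build_model,
    compute_metrics,
)
from .fcbf import CandidateSet, FCBFSelector
from .pso import SelectionResult, SwarmConfig, pso_search
from .synthetic import ExpressionDataset

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "HybridGeneSelector",
    "HybridRunResult",
    "load_dataset",
    "save_dataset",
    "run_hybrid",
    "stage_seed",
]


def stage_seed(master: int | None, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) from the master seed.

    Uses a CRC of the stage name so stages can be re-run in isolation with
    the same stream they received inside the full pipeline.
    """
    if master is None:
        master = 0
    ss = np.random.SeedSequence([int(master) % (2**31), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_dataset(matrix_path, labels_path, genes_as_rows: bool = False) -> ExpressionDataset:
    """Load a TSV expression matrix and labels, inner-joined on sample_id.

    The matrix file has a header of gene identifiers and a leading
    ``sample_id`` column (orientation flipped with ``genes_as_rows``); the
    labels file has columns ``sample_id`` and ``label`` with binary labels
    (1 = ruptured / case).  Row and column order follow file order.
    """
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):  # pandas would silently mangle these
        raise ValueError("duplicate gene/sample identifiers in matrix header")
    mat = pd.read_csv(matrix_path, sep="\t")
    if genes_as_rows:
        mat = mat.set_index(mat.columns[0]).T.rename_axis("sample_id").reset_index()
    if mat.columns[0] != "sample_id":
        mat = mat.rename(columns={mat.columns[0]: "sample_id"})
    genes = list(mat.columns[1:])
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers in matrix header")
    if mat["sample_id"].duplicated().any():
        dup = mat.loc[mat["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample identifier {dup!r} in matrix")

    lab = pd.read_csv(labels_path, sep="\t")
    lab.columns = ["sample_id", "label"] + list(lab.columns[2:])
    if lab["sample_id"].duplicated().any():
        dup = lab.loc[lab["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample identifier {dup!r} in labels")
    bad = lab[~lab["label"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"non-binary label {bad['label'].iloc[0]!r} for sample "
            f"{bad['sample_id'].iloc[0]!r}"
        )

    merged = mat.merge(lab[["sample_id", "label"]], on="sample_id", how="inner")
    if merged.empty:
        raise ValueError("matrix and labels share no sample identifiers")
    if len(merged) < len(mat) or len(merged) < len(lab):
        log.warning(
            "inner join kept %d of %d matrix / %d label samples",
            len(merged), len(mat), len(lab),
        )
    else:
        log.info("joined %d samples on sample_id", len(merged))
    values = merged[genes].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing or non-numeric value for sample {merged['sample_id'].iloc[i]!r}, "
            f"gene {genes[j]!r}"
        )
    return ExpressionDataset(
        matrix=values,
        sample_ids=list(merged["sample_id"]),
        gene_ids=genes,
        labels=merged["label"].to_numpy(dtype=int),
    )


def save_dataset(dataset: ExpressionDataset, out_dir, truth: pd.DataFrame | None = None) -> dict:
    """Write matrix.tsv / labels.tsv (and truth_roles.tsv) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": out / "matrix.tsv", "labels": out / "labels.tsv"}
    dataset.to_frame().to_csv(paths["matrix"], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame({"sample_id": dataset.sample_ids, "label": dataset.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    if truth is not None:
        paths["truth"] = out / "truth_roles.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable configuration of a full hybrid run."""

    # Stage 1 (FCBF)
    delta: float = 0.0
    discretization: str = "mdl"
    n_bins: int = 10
    # Stage 2 (PSO + MLP)
    n_particles: int = 30
    n_iterations: int = 100
    omega: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 0.6
    decode_threshold: float = 0.5
    turbulence: float = 0.05
    wrapper_cv: int = 5
    lambda_mse: float = 0.1
    lambda_size: float = 0.05
    hidden_size: int = 10
    learning_rate: float = 0.1
    epochs: int = 300
    # Stage 3 (benchmark)
    benchmark_folds: int = 10
    protocol: str = "paper"
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("paper", "nested"):
            raise ValueError("protocol must be 'paper' or 'nested'")

    def mlp_config(self) -> dict:
        return {
            "hidden_size": self.hidden_size,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# The two-stage selector as one estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y


class HybridGeneSelector(SelectorMixin, BaseEstimator):
    """FCBF filter followed by the PSO/MLP wrapper, as one selector.

    ``random_state`` is the master seed; the FCBF stage is deterministic and
    the wrapper stage receives a seed derived from it, so two fits with the
    same data and seed are identical.

    Attributes
    ----------
    fcbf_ : fitted FCBFSelector (stage 1).
    candidates_ : CandidateSet surviving the filter.
    result_ : SelectionResult of the swarm (stage 2).
    support_ : boolean mask over the input columns.
    """

    def __init__(
        self,
        delta: float = 0.0,
        discretization: str = "mdl",
        n_bins: int = 10,
        n_particles: int = 30,
        n_iterations: int = 100,
        omega: float = 0.7,
        c1: float = 2.0,
        c2: float = 2.0,
        v_max: float = 0.6,
        decode_threshold: float = 0.5,
        turbulence: float = 0.05,
        wrapper_cv: int = 5,
        lambda_mse: float = 0.1,
        lambda_size: float = 0.05,
        mlp_config: dict | None = None,
        random_state: int | None = None,
    ):
        self.delta = delta
        self.discretization = discretization
        self.n_bins = n_bins
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.omega = omega
        self.c1 = c1
        self.c2 = c2
        self.v_max = v_max
        self.decode_threshold = decode_threshold
        self.turbulence = turbulence
        self.wrapper_cv = wrapper_cv
        self.lambda_mse = lambda_mse
        self.lambda_size = lambda_size
        self.mlp_config = mlp_config
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.fcbf_ = FCBFSelector(
            delta=self.delta, discretization=self.discretization, n_bins=self.n_bins
        ).fit(X, y)
        cand_idx = self.fcbf_.selected_indices_
        if cand_idx.size == 0:
            raise ValueError("Stage 1 returned no candidates; lower delta")
        log.info("FCBF kept %d of %d genes", cand_idx.size, X.shape[1])
        cfg = SwarmConfig(
            n_particles=self.n_particles,
            n_iterations=self.n_iterations,
            omega=self.omega,
            c1=self.c1,
            c2=self.c2,
            v_max=self.v_max,
            decode_threshold=self.decode_threshold,
            turbulence=self.turbulence,
            seed=stage_seed(self.random_state, "pso"),
        )
        self.result_ = pso_search(
            list(cand_idx), X[:, cand_idx], y, cfg=cfg,
            mlp_config=self.mlp_config, cv=self.wrapper_cv,
            lambda_mse=self.lambda_mse, lambda_size=self.lambda_size,
        )
        self.candidates_ = self.fcbf_.candidates_
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[np.array(self.result_.selected_genes, dtype=int)] = True
        self.support_ = mask
        self.selected_indices_ = np.array(self.result_.selected_genes, dtype=int)
        self.n_features_in_ = X.shape[1]
        log.info("wrapper selected %d genes", mask.sum())
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class HybridRunResult:
    selected_genes: list
    candidates: CandidateSet
    candidate_gene_ids: list
    selection: SelectionResult
    report_before: BenchmarkReport
    report_after: BenchmarkReport
    config: RunConfig
    per_fold_subsets: list = field(default_factory=list)  # nested protocol only


def _selector_from_config(config: RunConfig) -> HybridGeneSelector:
    return HybridGeneSelector(
        delta=config.delta,
        discretization=config.discretization,
        n_bins=config.n_bins,
        n_particles=config.n_particles,
        n_iterations=config.n_iterations,
        omega=config.omega,
        c1=config.c1,
        c2=config.c2,
        v_max=config.v_max,
        decode_threshold=config.decode_threshold,
        turbulence=config.turbulence,
        wrapper_cv=config.wrapper_cv,
        lambda_mse=config.lambda_mse,
        lambda_size=config.lambda_size,
        mlp_config=config.mlp_config(),
        random_state=config.seed,
    )


def _nested_benchmark(dataset: ExpressionDataset, config: RunConfig):
    """Selection repeated inside each outer training fold; metrics from
    outer test folds only."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X, y = dataset.matrix, dataset.labels
    bench_seed = stage_seed(config.seed, "benchmark")
    outer = StratifiedKFold(
        n_splits=config.benchmark_folds, shuffle=True, random_state=bench_seed
    )
    preds = {m: np.empty(len(y), dtype=int) for m in MODEL_NAMES}
    fold_aucs = {m: [] for m in MODEL_NAMES}
    per_fold_subsets = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        fold_cfg_seed = stage_seed(config.seed, f"nested-fold-{f}")
        selector = _selector_from_config(config)
        selector.set_params(random_state=fold_cfg_seed)
        selector.fit(X[tr], y[tr])
        cols = selector.selected_indices_
        per_fold_subsets.append([dataset.gene_ids[j] for j in cols])
        for name in MODEL_NAMES:
            model = build_model(name, seed=bench_seed)
            with _quiet_fit():
                model.fit(X[np.ix_(tr, cols)], y[tr])
                te_X = X[np.ix_(te, cols)]
                if hasattr(model, "predict_proba"):
                    score = model.predict_proba(te_X)[:, 1]
                else:
                    score = model.decision_function(te_X)
                preds[name][te] = model.predict(te_X)
            fold_aucs[name].append(float(roc_auc_score(y[te], score)))
    rows, confusions = [], {}
    for name in MODEL_NAMES:
        m = compute_metrics(y, preds[name])
        aucs = np.array(fold_aucs[name])
        rows.append(
            {
                "model": name,
                "accuracy": m["accuracy"],
                "recall": m["recall"],
                "precision": m["precision"],
                "f1": m["f1"],
                "auc_mean": float(aucs.mean()),
                "auc_sd": float(aucs.std(ddof=1)),
            }
        )
        confusions[name] = m["confusion"]
    table = pd.DataFrame(rows)
    mean = table.drop(columns="model").mean()
    table = pd.concat(
        [table, pd.DataFrame([{"model": "Mean", **mean.to_dict()}])], ignore_index=True
    )
    report = BenchmarkReport(
        table=table, confusions=confusions, k=config.benchmark_folds, seed=bench_seed
    )
    return report, per_fold_subsets


def run_hybrid(dataset: ExpressionDataset, config: RunConfig, out_dir=None) -> HybridRunResult:
    """Run FCBF → PSO/MLP → benchmark; optionally write all artifact files.

    Under the ``paper`` protocol the final subset is selected once on all
    samples and both benchmarks are plain k-fold CV; under ``nested`` the
    after-selection benchmark repeats selection inside each training fold.
    """
    X, y = dataset.matrix, dataset.labels
    bench_seed = stage_seed(config.seed, "benchmark")

    selector = _selector_from_config(config)
    selector.fit(X, y)
    candidate_ids = [dataset.gene_ids[j] for j in selector.fcbf_.selected_indices_]
    selected_ids = [dataset.gene_ids[j] for j in selector.selected_indices_]
    log.info(
        "pipeline narrowing: %d genes -> %d candidates -> %d selected",
        len(dataset.gene_ids), len(candidate_ids), len(selected_ids),
    )

    report_before = benchmark_suite(
        X, y, gene_ids=dataset.gene_ids, subset="all",
        k=config.benchmark_folds, seed=bench_seed,
    )
    per_fold_subsets: list = []
    if config.protocol == "nested":
        report_after, per_fold_subsets = _nested_benchmark(dataset, config)
    else:
        report_after = benchmark_suite(
            X, y, gene_ids=dataset.gene_ids, subset=selected_ids,
            k=config.benchmark_folds, seed=bench_seed,
        )

    result = HybridRunResult(
        selected_genes=selected_ids,
        candidates=selector.candidates_,
        candidate_gene_ids=candidate_ids,
        selection=selector.result_,
        report_before=report_before,
        report_after=report_after,
        config=config,
        per_fold_subsets=per_fold_subsets,
    )
    if out_dir is not None:
        _write_artifacts(result, dataset, Path(out_dir))
    return result


def _write_artifacts(result: HybridRunResult, dataset: ExpressionDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    su = result.candidates.su_with_class
    idx = {g: j for j, g in enumerate(dataset.gene_ids)}
    pd.DataFrame(
        {
            "gene_id": result.candidate_gene_ids,
            "su_with_class": [
                su[f"g{idx[g]:05d}"] for g in result.candidate_gene_ids
            ],
            "rank": range(1, len(result.candidate_gene_ids) + 1),
        }
    ).to_csv(out / "candidates_ranked.tsv", sep="\t", index=False, float_format="%.6f")

    (out / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in result.selected_genes)
    )

    detail = result.selection.gbest_detail_history
    pd.DataFrame(
        {
            "iteration": range(len(detail)),
            "gbest_composite": [f.composite for f in detail],
            "gbest_acc": [f.accuracy for f in detail],
            "gbest_mse": [f.mse for f in detail],
            "gbest_size": [f.subset_size for f in detail],
        }
    ).to_csv(out / "fitness_history.tsv", sep="\t", index=False, float_format="%.6f")

    result.report_after.to_tsv(out / "benchmark_report.tsv")
    result.report_before.to_tsv(out / "benchmark_report_before.tsv")
    for name, cm in result.report_after.confusions.items():
        pd.DataFrame(cm, index=["true_0", "true_1"], columns=["pred_0", "pred_1"]).to_csv(
            out / f"confusion_{name}.tsv", sep="\t"
        )

    import lightgbm
    import sklearn
    import xgboost

    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(dataset.matrix).tobytes())
    digest.update(np.ascontiguousarray(dataset.labels).tobytes())
    manifest = {
        "config": asdict(result.config),
        "stage_seeds": {
            "pso": stage_seed(result.config.seed, "pso"),
            "benchmark": stage_seed(result.config.seed, "benchmark"),
        },
        "versions": {
            "genesift": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
            "lightgbm": lightgbm.__version__,
        },
        "input_sha256": digest.hexdigest(),
        "n_samples": dataset.n_samples,
        "n_genes": dataset.n_genes,
        "n_candidates": len(result.candidate_gene_ids),
        "n_selected": len(result.selected_genes),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
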