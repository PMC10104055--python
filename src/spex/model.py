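"""Gradient-boosted tree regression of log-expression on flattened tensors.

Expression is modelled on the log10(x + pseudocount) scale (pseudocount
1e-4 by default, the ExPecto convention), with squared-error gradient
boosting over trees (XGBoost, histogram method). Evaluation is the Spearman
rank correlation between predicted and observed log-expression on a
held-out chromosome set — chr8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb
from scipy import stats

from .genome_io import ExpressionTable
from .tensors import GeneTensor

__all__ = ["ModelConfig", "SplitSpec", "Design", "TrainedModel", "make_design", "train", "evaluate_spearman"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the boosted-tree regressor.

    ``subsample`` < 1 makes the fit depend on ``seed``, which is what gives
    repeated trainings their run-to-run variability; the histogram tree
    method is the CPU analogue of the GPU histogram split finder and can be
    switched with ``tree_method``.
    """

    learning_rate: float = 0.1
    max_depth: int = 4
    n_rounds: int = 150
    subsample: float = 0.8
    seed: int = 0
    tree_method: str = "hist"
    nthread: int = 0  # 0 = xgboost default (all cores)

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")

    def xgb_params(self) -> dict:
        params = {
            "objective": "reg:squarederror",
            "booster": "gbtree",
            "tree_method": self.tree_method,
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.subsample,
            "seed": self.seed,
        }
        if self.nthread:
            params["nthread"] = self.nthread
        return params


@dataclass(frozen=True)
class SplitSpec:
    """Hold out whole chromosomes as the test set (default chr8)."""

    test_chroms: frozenset = frozenset({"chr8"})

    def is_test(self, chrom: str) -> bool:
        return chrom in self.test_chroms


@dataclass
class Design:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_genes: list[str]
    test_genes: list[str]
    pseudocount: float


@dataclass
class TrainedModel:
    booster: xgb.Booster
    n_inputs: int
    train_genes: list[str]
    config: ModelConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"model expects {self.n_inputs} inputs, got {X.shape[1]}")
        return self.booster.predict(xgb.DMatrix(X))


def make_design(
    tensors: dict[str, GeneTensor],
    expression: ExpressionTable,
    gene_chroms: dict[str, str],
    split: SplitSpec = SplitSpec(),
    pseudocount: float = 1e-4,
) -> Design:
    """Flatten tensors into a design matrix and log-transform expression.

    Rows are row-major (feature-major) flattened tensors; genes are sorted
    by gene_id for a deterministic order and partitioned into train/test by
    chromosome. Every tensor gene must have an expression value and a
    chromosome, and all tensors must share F and the column count.
    """
    if not tensors:
        raise ValueError("no tensors given")
    missing = sorted(g for g in tensors if g not in expression)
    if missing:
        raise ValueError(f"genes without expression values: {missing}")
    shapes = {t.values.shape for t in tensors.values()}
    if len(shapes) > 1:
        raise ValueError(f"tensors have mixed shapes: {sorted(shapes)}")

    train_X, train_y, train_g = [], [], []
    test_X, test_y, test_g = [], [], []
    for gid in sorted(tensors):
        row = tensors[gid].values.reshape(-1)
        y = np.log10(expression[gid] + pseudocount)
        if split.is_test(gene_chroms[gid]):
            test_X.append(row), test_y.append(y), test_g.append(gid)
        else:
            train_X.append(row), train_y.append(y), train_g.append(gid)

    width = next(iter(shapes))[0] * next(iter(shapes))[1]
    return Design(
        X_train=np.asarray(train_X, dtype=float).reshape(len(train_g), width),
        y_train=np.asarray(train_y, dtype=float),
        X_test=np.asarray(test_X, dtype=float).reshape(len(test_g), width),
        y_test=np.asarray(test_y, dtype=float),
        train_genes=train_g,
        test_genes=test_g,
        pseudocount=pseudocount,
    )


def train(design: Design, config: ModelConfig = ModelConfig()) -> TrainedModel:
    if len(design.train_genes) < 2:
        raise ValueError("need at least 2 training genes")
    if not (np.all(np.isfinite(design.X_train)) and np.all(np.isfinite(design.y_train))):
        raise ValueError("non-finite values in the training design")
    dtrain = xgb.DMatrix(design.X_train, label=design.y_train)
    booster = xgb.train(config.xgb_params(), dtrain, num_boost_round=config.n_rounds)
    return TrainedModel(
        booster=booster,
        n_inputs=design.X_train.shape[1],
        train_genes=list(design.train_genes),
        config=config,
    )


def evaluate_spearman(model: TrainedModel, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Spearman rank correlation of predictions vs observed (average ranks on ties).

    Constant predictions or constant observations make the correlation
    undefined and raise rather than silently returning 0.
    """
    if len(y_test) < 3:
        raise ValueError("need at least 3 test genes")
    pred = model.predict(X_test)
    if np.ptp(pred) == 0 or np.ptp(y_test) == 0:
        raise ValueError("Spearman undefined: constant predictions or observations")
    rho = stats.spearmanr(pred, y_test).statistic
    return float(rho)
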