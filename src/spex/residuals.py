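"""Per-gene residual diagnostics across factor models.

Residuals are observed − predicted log-expression on the held-out genes.
Across the factor-specific spatial models (cohesin, CTCF, RNAPOL2), the
per-gene residual closest to zero is "best" (the gene's expression is
explained by at least one protein's contact map); a symmetric cutoff of
k·SD (k = 0.5) of that best-residual distribution, centred at zero,
classifies genes as well-predicted under the spatial models, the baseline,
both, or neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ResidualTable",
    "BestResidual",
    "CutoffReport",
    "compute_residuals",
    "anderson_darling",
    "spex_best",
    "cutoff_classify",
    "residual_report",
]


@dataclass
class ResidualTable:
    """Observed y, and per-model predicted y / residual, for one gene set."""

    genes: list[str]
    observed: np.ndarray  # (n,)
    predicted: dict[str, np.ndarray]  # label -> (n,)

    def residual(self, label: str) -> np.ndarray:
        return self.observed - self.predicted[label]

    @property
    def labels(self) -> list[str]:
        return list(self.predicted)


@dataclass
class BestResidual:
    genes: list[str]
    best: np.ndarray  # signed residual with smallest |r| per gene
    winner: list[str]
    ties: list[bool]


@dataclass
class CutoffReport:
    k: float
    sd: float
    half_width: float
    within_spex: int
    within_baseline: int
    both: int
    spex_only: int
    baseline_only: int
    classes: dict[str, list[str]] = field(default_factory=dict)


def compute_residuals(models: dict, designs: dict, observed_label: str | None = None) -> ResidualTable:
    """r(g, m) = y(g) − ŷ_m(g) over the test genes, for every model.

    ``models`` maps label → TrainedModel and ``designs`` maps the same labels
    to the Design whose test block matches that model's input width (the
    baseline model takes the 10-column design, the spatial models the
    11-column one). All designs must list the same test genes with the same
    observed values.
    """
    if set(models) != set(designs):
        raise ValueError("models and designs must share labels")
    labels = list(models)
    ref = designs[labels[0]]
    genes = list(ref.test_genes)
    observed = np.asarray(ref.y_test, dtype=float)
    predicted = {}
    for label in labels:
        d = designs[label]
        if list(d.test_genes) != genes or not np.array_equal(d.y_test, observed):
            raise ValueError(f"design {label!r} disagrees on test genes/observations")
        predicted[label] = np.asarray(models[label].predict(d.X_test), dtype=float)
    return ResidualTable(genes=genes, observed=observed, predicted=predicted)


def anderson_darling(residuals) -> tuple[float, dict[float, bool]]:
    """Anderson–Darling normality test with estimated mean and variance.

    Returns the A² statistic and, for each standard significance level
    (15, 10, 5, 2.5, 1 %), whether normality is rejected there.
    """
    x = np.asarray(residuals, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 residuals")
    if np.ptp(x) == 0:
        raise ValueError("constant residuals: normality test undefined")
    import warnings

    with warnings.catch_warnings():
        # the fixed-critical-value API is the intended usage here
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(x, dist="norm")
    rejected = {
        float(lvl): bool(res.statistic > crit)
        for lvl, crit in zip(res.significance_level, res.critical_values)
    }
    return float(res.statistic), rejected


def spex_best(table: ResidualTable, factor_labels: list[str]) -> BestResidual:
    """Per gene, the factor residual closest to zero; ties go to the first label."""
    if not factor_labels:
        raise ValueError("need at least one factor model")
    resid = np.stack([table.residual(lbl) for lbl in factor_labels])  # (m, n)
    absr = np.abs(resid)
    idx = np.argmin(absr, axis=0)  # argmin takes the first minimum: label order
    n = len(table.genes)
    best = resid[idx, np.arange(n)]
    min_abs = absr[idx, np.arange(n)]
    ties = [(np.isclose(absr[:, g], min_abs[g]).sum() > 1) for g in range(n)]
    winner = [factor_labels[i] for i in idx]
    return BestResidual(genes=list(table.genes), best=best, winner=winner, ties=ties)


def cutoff_classify(best: BestResidual, baseline_residuals, k: float = 0.5) -> CutoffReport:
    """Classify genes by the symmetric k·SD cutoff of the best-residual distribution.

    Half-width h = k × sample SD (ddof 1) of the best residuals; the interval
    [−h, +h] is centred at zero. A gene is "within" for a model iff its
    residual under that model lands in the interval; the classes both /
    spex_only / baseline_only partition accordingly.
    """
    rb = np.asarray(baseline_residuals, dtype=float)
    if len(rb) != len(best.genes):
        raise ValueError("baseline residuals must cover the same genes")
    sd = float(np.std(best.best, ddof=1))
    if sd == 0:
        raise ValueError("zero SD of best residuals: cutoff undefined")
    h = k * sd
    in_spex = np.abs(best.best) <= h
    in_base = np.abs(rb) <= h
    genes = np.asarray(best.genes)
    classes = {
        "both": list(genes[in_spex & in_base]),
        "spex_only": list(genes[in_spex & ~in_base]),
        "baseline_only": list(genes[~in_spex & in_base]),
    }
    return CutoffReport(
        k=k,
        sd=sd,
        half_width=h,
        within_spex=int(in_spex.sum()),
        within_baseline=int(in_base.sum()),
        both=len(classes["both"]),
        spex_only=len(classes["spex_only"]),
        baseline_only=len(classes["baseline_only"]),
        classes=classes,
    )


def residual_report(
    table: ResidualTable,
    best: BestResidual,
    report: CutoffReport,
    baseline_label: str,
    path: str | None = None,
) -> pd.DataFrame:
    """Per-gene table (observed, per-model prediction/residual, best, class).

    Writes a TSV when ``path`` is given, with a ``# summary`` comment block
    (SD, half-width, class counts) ahead of the header.
    """
    df = pd.DataFrame({"gene_id": table.genes, "observed": table.observed})
    for label in table.labels:
        df[f"pred_{label}"] = table.predicted[label]
        df[f"resid_{label}"] = table.residual(label)
    df["best_residual"] = best.best
    df["best_factor"] = best.winner
    df["best_tie"] = best.ties

    cls = np.full(len(df), "neither", dtype=object)
    for name in ("both", "spex_only", "baseline_only"):
        cls[np.isin(df["gene_id"], report.classes[name])] = name
    df["class"] = cls

    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# k={report.k} sd={report.sd:.10g} half_width={report.half_width:.10g}\n")
            fh.write(
                f"# within_spex={report.within_spex} within_baseline={report.within_baseline} "
                f"both={report.both} spex_only={report.spex_only} "
                f"baseline_only={report.baseline_only}\n"
            )
            fh.write(f"# baseline_model={baseline_label}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return df
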