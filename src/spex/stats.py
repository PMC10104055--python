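"""Repeated-training experiments and their significance testing.

The baseline (F×10) and spatial (F×11) arms are each trained ``n_runs``
times with per-run seeds base_seed + i (the same seed in both arms), scored
by test-set Spearman correlation, and the two score distributions compared
with Welch's unequal-variance t-test; Bonferroni correction is applied
across however many comparisons one invocation emits. Experiments can be
pooled by mediating factor (cohesin / CTCF / RNAPOL2) and overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .model import Design, ModelConfig, evaluate_spearman, train

__all__ = [
    "ScoreDistribution",
    "ComparisonResult",
    "run_repeated",
    "welch_test",
    "bonferroni",
    "compare_arms",
    "group_test",
]


@dataclass
class ScoreDistribution:
    label: str
    scores: list[float]
    seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.seeds):
            raise ValueError("one score per seed required")
        if any(not -1 <= s <= 1 for s in self.scores):
            raise ValueError("Spearman scores must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))


@dataclass
class ComparisonResult:
    baseline_label: str
    spatial_label: str
    mean_baseline: float
    mean_spatial: float
    mean_improvement: float
    t: float
    df: float
    p_raw: float
    p_adj: float | None
    n_baseline: int
    n_spatial: int


def _subsampled(design: Design, idx: np.ndarray) -> Design:
    return Design(
        X_train=design.X_train[idx],
        y_train=design.y_train[idx],
        X_test=design.X_test,
        y_test=design.y_test,
        train_genes=[design.train_genes[i] for i in idx],
        test_genes=design.test_genes,
        pseudocount=design.pseudocount,
    )


def run_repeated(
    design_baseline: Design,
    design_spatial: Design,
    config: ModelConfig = ModelConfig(),
    n_runs: int = 25,
    base_seed: int = 0,
    label: str = "experiment",
    train_frac: float = 0.5,
) -> tuple[ScoreDistribution, ScoreDistribution]:
    """Train both arms n_runs times; run i uses seed base_seed + i in each arm.

    Each run is a Monte-Carlo cross-validation replicate: a seeded random
    ``train_frac`` subset of the training genes is drawn (the same subset in
    both arms, so runs are paired) and both models are fit on it and scored
    on the full held-out chromosome set. The subset draw plus XGBoost's row
    subsampling are what make repeated runs vary; without such run-level
    stochasticity every repetition of a deterministic CPU fit would return
    the same score and the Welch comparison would be degenerate.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    if design_baseline.train_genes != design_spatial.train_genes:
        raise ValueError("arms must be built over the same training genes")
    n_train = len(design_baseline.train_genes)
    n_sub = max(2, int(round(train_frac * n_train)))
    base_scores, spatial_scores, seeds = [], [], []
    for i in range(n_runs):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_train, size=n_sub, replace=False)
        cfg = replace(config, seed=seed)
        try:
            mb = train(_subsampled(design_baseline, idx), cfg)
            ms = train(_subsampled(design_spatial, idx), cfg)
            base_scores.append(evaluate_spearman(mb, design_baseline.X_test, design_baseline.y_test))
            spatial_scores.append(evaluate_spearman(ms, design_spatial.X_test, design_spatial.y_test))
        except Exception as exc:
            raise RuntimeError(f"run with seed {seed} failed: {exc}") from exc
        seeds.append(seed)
    return (
        ScoreDistribution(f"{label}:baseline", base_scores, seeds),
        ScoreDistribution(f"{label}:spatial", spatial_scores, seeds),
    )


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, p_raw, df) with t = (mean_a − mean_b)/√(s²_a/n_a + s²_b/n_b)
    and Welch–Satterthwaite degrees of freedom. Two arms with zero variance
    and equal means give (0, 1, ·) by convention; zero variance otherwise is
    an error (the statistic would be infinite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, float(na + nb - 2)
        raise ValueError("zero variance in both arms with unequal means")
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one arm; Welch statistic undefined")
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def bonferroni(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Set p_adj = min(1, p_raw · m) across the m results, order preserved."""
    m = len(results)
    if m < 1:
        raise ValueError("need at least one comparison")
    for r in results:
        r.p_adj = min(1.0, r.p_raw * m)
    return results


def compare_arms(baseline: ScoreDistribution, spatial: ScoreDistribution) -> ComparisonResult:
    """Welch comparison of one spatial arm against its baseline (p_adj unset)."""
    t, p, df = welch_test(spatial.scores, baseline.scores)
    return ComparisonResult(
        baseline_label=baseline.label,
        spatial_label=spatial.label,
        mean_baseline=baseline.mean,
        mean_spatial=spatial.mean,
        mean_improvement=spatial.mean - baseline.mean,
        t=t,
        df=df,
        p_raw=p,
        p_adj=None,
        n_baseline=len(baseline.scores),
        n_spatial=len(spatial.scores),
    )


def group_test(
    groups: dict[str, list[tuple[ScoreDistribution, ScoreDistribution]]],
    include_overall: bool = True,
) -> list[ComparisonResult]:
    """Pool baseline vs spatial scores within each factor group, test, correct.

    Each group's baseline scores are concatenated across its experiments and
    tested against the pooled spatial scores; an ``all`` group pooling every
    experiment is appended when ``include_overall``. Bonferroni is applied
    across the emitted comparisons.
    """
    if not groups or any(not v for v in groups.values()):
        raise ValueError("every group must contain at least one experiment")
    pooled: list[tuple[str, list[float], list[float]]] = []
    for factor, pairs in groups.items():
        base = [s for b, _s in pairs for s in b.scores]
        spat = [s for _b, s in pairs for s in s.scores]
        pooled.append((factor, base, spat))
    if include_overall:
        base = [s for pairs in groups.values() for b, _ in pairs for s in b.scores]
        spat = [s for pairs in groups.values() for _, sp in pairs for s in sp.scores]
        pooled.append(("all", base, spat))

    results = []
    for factor, base, spat in pooled:
        t, p, df = welch_test(spat, base)
        results.append(
            ComparisonResult(
                baseline_label=f"{factor}:baseline",
                spatial_label=f"{factor}:spatial",
                mean_baseline=float(np.mean(base)),
                mean_spatial=float(np.mean(spat)),
                mean_improvement=float(np.mean(spat) - np.mean(base)),
                t=t,
                df=df,
                p_raw=p,
                p_adj=None,
                n_baseline=len(base),
                n_spatial=len(spat),
            )
        )
    return bonferroni(results)
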