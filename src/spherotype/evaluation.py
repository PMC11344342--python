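"""Evaluation surfaces: counting agreement, accuracy summaries, ablations.

Mirrors how the pipeline is validated: agreement between automatic and
manual (or roster) cell counts per tile, median accuracy with a bootstrap
confidence interval across training runs, and ablations over input channels
and training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CHANNEL_ORDER, CellSample
from .nn.model import ModelConfig
from .nn.train import TrainingRunResult, train_bootstrap


@dataclass
class CountPair:
    image_id: str
    manual_count: int
    auto_count: int

    def __post_init__(self) -> None:
        if self.manual_count < 0 or self.auto_count < 0:
            raise ValueError("counts must be non-negative")


def count_agreement(pairs: list[CountPair]) -> dict:
    """Automatic/manual counting agreement over tile images.

    Returns the pooled ratio (sum auto / sum manual), the R^2 of the
    least-squares regression of auto on manual, per-image ratios, and
    per-image residuals of the fit.
    """
    from scipy import stats

    if len(pairs) < 2:
        raise ValueError("need at least two count pairs")
    manual = np.array([p.manual_count for p in pairs], dtype=float)
    auto = np.array([p.auto_count for p in pairs], dtype=float)
    if manual.sum() == 0:
        raise ValueError("total manual count is zero")
    if np.unique(manual).size > 1:
        fit = stats.linregress(manual, auto)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        residuals = (auto - (slope * manual + intercept)).tolist()
    else:  # identical manual counts: the regression is undefined
        slope = intercept = r2 = float("nan")
        residuals = [float("nan")] * len(pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_image = np.where(manual > 0, auto / manual, np.nan)
    return {
        "ratio": float(auto.sum() / manual.sum()),
        "r_squared": float(r2),
        "slope": float(slope),
        "intercept": float(intercept),
        "per_image_ratio": per_image.tolist(),
        "residuals": residuals,
    }


def accuracy_summary(
    run_results: list[TrainingRunResult],
    n_boot: int = 10_000,
    seed: int = 0,
    which: str = "strict",
) -> dict:
    """Median/max accuracy across runs with a bootstrap 95% CI of the median.

    ``which`` selects strict-test accuracies (default) or per-run test
    accuracies.  The CI uses the seeded percentile bootstrap.
    """
    if not run_results:
        raise ValueError("no run results")
    if which == "strict":
        accs = np.array([
            r.strict_accuracy for r in run_results if r.strict_accuracy is not None
        ])
    else:
        accs = np.array([r.test_accuracy for r in run_results])
    if accs.size == 0:
        raise ValueError(f"no {which} accuracies recorded")
    lo, hi = bootstrap_median_ci(accs, n_boot=n_boot, seed=seed)
    return {
        "median": float(np.median(accs)),
        "max": float(accs.max()),
        "ci95_low": lo,
        "ci95_high": hi,
        "n_runs": int(accs.size),
        "values": accs.tolist(),
    }


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the median (seeded, resample medians)."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    return float(np.percentile(medians, 2.5)), float(np.percentile(medians, 97.5))


@dataclass
class AblationResult:
    channel_subset: tuple[str, ...]
    accuracies: list[float] = field(default_factory=list)
    median: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))


def zero_channels(samples: list[CellSample], keep: tuple[str, ...]) -> list[CellSample]:
    """Copies of the samples with all channels outside ``keep`` zeroed.

    Tensor shape is preserved so one architecture serves every subset; the
    zeroed channels carry no information by construction.
    """
    drop = [i for i, ch in enumerate(CHANNEL_ORDER) if ch not in keep]
    if len(drop) == len(CHANNEL_ORDER):
        raise ValueError("channel subset must be non-empty")
    out = []
    for s in samples:
        t = None
        if s.tensor is not None:
            t = s.tensor.copy()
            t[drop] = 0.0
        out.append(replace(s, tensor=t))
    return out


def channel_ablation(
    working: list[CellSample],
    strict: list[CellSample],
    config: ModelConfig,
    subsets: list[tuple[str, ...]],
    runs_per_subset: int = 1,
    epochs: int | None = None,
) -> list[AblationResult]:
    """Retrain with channel subsets (absent channels zeroed) and summarize."""
    out = []
    for subset in subsets:
        subset = tuple(subset)
        for ch in subset:
            if ch not in CHANNEL_ORDER:
                raise ValueError(f"unknown channel {ch!r}")
        w = zero_channels(working, subset)
        s = zero_channels(strict, subset)
        _, results = train_bootstrap(
            w, config, strict=s, n_runs=runs_per_subset, epochs=epochs
        )
        accs = [r.strict_accuracy for r in results if r.strict_accuracy is not None]
        res = AblationResult(channel_subset=subset, accuracies=accs)
        if accs:
            res.median = float(np.median(accs))
            if len(accs) > 1:
                res.ci95 = bootstrap_median_ci(np.array(accs), seed=config.seed)
        out.append(res)
    return out


def data_size_ablation(
    working: list[CellSample],
    strict: list[CellSample],
    config: ModelConfig,
    fractions: tuple[float, ...] = (0.1, 0.5, 1.0),
    seed: int = 0,
    runs_per_fraction: int = 1,
    epochs: int | None = None,
) -> dict[float, float]:
    """Strict-test accuracy when training on a fraction of the cells.

    Subsets are drawn at the cell level (all rotations of a cell follow it),
    so reduced datasets remain leak-free.
    """
    rng = np.random.default_rng(seed)
    cells = sorted({s.cell_key for s in working})
    out = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        if frac == 1.0:
            subset = working
        else:
            n = max(int(round(frac * len(cells))), 2)
            chosen_idx = rng.choice(len(cells), size=n, replace=False)
            chosen = {cells[i] for i in chosen_idx}
            subset = [s for s in working if s.cell_key in chosen]
        if len(subset) < config.batch_size:
            raise ValueError(f"fraction {frac} yields fewer than one batch")
        _, results = train_bootstrap(
            subset, config, strict=strict, n_runs=runs_per_fraction, epochs=epochs
        )
        accs = [r.strict_accuracy for r in results if r.strict_accuracy is not None]
        out[frac] = float(np.median(accs)) if accs else float("nan")
    return out
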