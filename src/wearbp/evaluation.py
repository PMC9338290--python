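"""Agreement statistics and bootstrap model comparison.

Metrics between device/model estimates p_i and reference readings y_i:

* MAD  = (1/n) sum |p_i - y_i|                 (mean absolute difference, mmHg)
* MAPD = (1/n) sum 100 |p_i - y_i| / y_i       (mean absolute % difference)
* RMSE = sqrt((1/n) sum (p_i - y_i)^2)         (mmHg)

plus Bland–Altman agreement (mean difference, SD, 1.96-SD limits of
agreement, Pearson r), condition-stratified reporting, a paired-bootstrap
RMSE comparison between two models evaluated on the same test observations
(superiority = upper 95% CI of the RMSE difference below 0 mmHg), and a
bootstrap confidence interval for the MAD.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

STRATA = ("overall", "static", "warm_rest", "cold_walk", "rest")


def _pairs(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must have equal length")
    if p.size == 0:
        raise ValueError("empty pair set")
    if not (np.isfinite(p).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in pairs")
    return p, y


def mad(p, y) -> float:
    """Mean absolute difference, mmHg."""
    p, y = _pairs(p, y)
    return float(np.mean(np.abs(p - y)))


def mapd(p, y) -> float:
    """Mean absolute percentage difference, %."""
    p, y = _pairs(p, y)
    if np.any(y == 0):
        raise ValueError("MAPD undefined for y_i = 0")
    return float(np.mean(100.0 * np.abs(p - y) / np.abs(y)))


def rmse(p, y) -> float:
    """Root-mean-square error, mmHg."""
    p, y = _pairs(p, y)
    return float(np.sqrt(np.mean((p - y) ** 2)))


def bland_altman(p, y) -> dict[str, float]:
    """Agreement statistics of differences p - y against the reference."""
    p, y = _pairs(p, y)
    d = p - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    if len(d) > 1 and np.std(p) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(p, y)[0, 1])
    else:
        r = float("nan")
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_lower": mean_diff - 1.96 * sd_diff,
        "loa_upper": mean_diff + 1.96 * sd_diff,
        "correlation": r,
    }


def stratified_report(pairs: pd.DataFrame) -> dict:
    """Per-stratum, per-split, per-target metric report.

    ``pairs`` needs columns: target ("sbp"/"dbp"), p, y, condition, split.
    The overall stratum is the union of the condition strata.  Bland–Altman
    and correlation are reported for the test split of each target.  Empty
    cells are reported with n = 0 and no metrics.
    """
    required = {"target", "p", "y", "condition", "split"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs missing columns: {sorted(required - set(pairs.columns))}")
    report: dict = {}
    for target, tdf in pairs.groupby("target"):
        tr: dict = {"strata": {}}
        for stratum in STRATA:
            sdf = tdf if stratum == "overall" else tdf[tdf["condition"] == stratum]
            cell: dict = {}
            for split in ("train", "test"):
                xdf = sdf[sdf["split"] == split]
                if len(xdf) == 0:
                    cell[split] = {"n": 0}
                    continue
                cell[split] = {
                    "n": int(len(xdf)),
                    "mad": mad(xdf["p"], xdf["y"]),
                    "mapd": mapd(xdf["p"], xdf["y"]),
                    "rmse": rmse(xdf["p"], xdf["y"]),
                }
            tr["strata"][stratum] = cell
        test_df = tdf[tdf["split"] == "test"]
        if len(test_df) > 0:
            tr["bland_altman_test"] = bland_altman(test_df["p"], test_df["y"])
        report[target] = tr
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a stratified report into a tidy table (one row per cell)."""
    rows = []
    for target, tr in report.items():
        for stratum, cell in tr["strata"].items():
            for split, stats in cell.items():
                rows.append({"target": target, "stratum": stratum,
                             "split": split, **stats})
    return pd.DataFrame(rows)


@dataclass
class BootstrapComparison:
    """Paired-bootstrap RMSE comparison of a model against a baseline."""

    target: str
    model_rmse: float
    model_ci: tuple[float, float]
    baseline_rmse: float
    baseline_ci: tuple[float, float]
    diff: float  # model - baseline, mmHg
    diff_ci: tuple[float, float]
    p_value: float
    superior: bool
    n_resamples: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def bootstrap_rmse_comparison(model_p, baseline_p, y,
                              n_resamples: int = 10_000, seed: int = 0,
                              target: str = "") -> BootstrapComparison:
    """Compare two models on the same test observations by bootstrap RMSE.

    Each resample draws test indices with replacement (sample size = test
    size) and applies the *same* indices to both models, so the distribution
    of the RMSE difference reflects paired errors.  Superiority of the model
    requires the upper 95% CI bound of (model - baseline) RMSE difference to
    lie below 0 mmHg; the p-value is the fraction of resamples with a
    difference >= 0 (floored at 1/n_resamples).
    """
    pm, y = _pairs(model_p, y)
    pb, _ = _pairs(baseline_p, y)
    n = len(y)
    err_m = (pm - y) ** 2
    err_b = (pb - y) ** 2
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    rmse_m = np.sqrt(err_m[idx].mean(axis=1))
    rmse_b = np.sqrt(err_b[idx].mean(axis=1))
    diff = rmse_m - rmse_b
    lo_m, hi_m = np.percentile(rmse_m, [2.5, 97.5])
    lo_b, hi_b = np.percentile(rmse_b, [2.5, 97.5])
    lo_d, hi_d = np.percentile(diff, [2.5, 97.5])
    p_value = max(float(np.mean(diff >= 0)), 1.0 / n_resamples)
    return BootstrapComparison(
        target=target,
        model_rmse=rmse(pm, y), model_ci=(float(lo_m), float(hi_m)),
        baseline_rmse=rmse(pb, y), baseline_ci=(float(lo_b), float(hi_b)),
        diff=rmse(pm, y) - rmse(pb, y), diff_ci=(float(lo_d), float(hi_d)),
        p_value=p_value, superior=bool(hi_d < 0),
        n_resamples=n_resamples, seed=seed,
    )


def bootstrap_mad_ci(p, y, n_iterations: int = 1_000,
                     seed: int = 0) -> tuple[float, float]:
    """95% percentile CI of the MAD from resampling with replacement."""
    p, y = _pairs(p, y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 pairs for a bootstrap CI")
    err = np.abs(p - y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iterations, n))
    mads = err[idx].mean(axis=1)
    lo, hi = np.percentile(mads, [2.5, 97.5])
    return float(lo), float(hi)
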