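"""Out-of-sample agreement statistics.

Pooled predicted-vs-observed Pearson correlation (both intra- and
inter-individual variability), per-person correlations (intraindividual
only), and their Fisher-z average: correlations do not combine linearly, so
per-person r's are mapped through z = atanh(r), averaged, and mapped back
with tanh.  CIs: Fisher-z normal interval z ± 1.96/sqrt(n-3) for a single
r; a t interval on the z scale (df = persons - 1) for the across-person
average.  Predictions are first averaged over the m imputation copies per
(person, hour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, InsufficientDataError, UndefinedCorrelationError


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class IdiographicSummary:
    per_person: dict[str, CorrelationResult]
    average_r: float
    average_ci: tuple[float, float]
    #: persons whose correlation was undefined or under-observed, excluded
    #: from the average and reported
    excluded: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def pool_imputations(records: pd.DataFrame) -> pd.DataFrame:
    """Average predictions over the m imputation copies per (person, hour).

    Observed outcomes are identical across copies (the outcome is never
    imputed), so their mean is a pass-through.  An inconsistent number of
    copies across person-hours is an alignment error.
    """
    if not len(records):
        return records.copy()
    counts = records.groupby(["person_id", "hour_index"])["imputation_id"].nunique()
    if counts.nunique() > 1:
        raise AlignmentError(
            f"inconsistent imputation counts across person-hours: {sorted(counts.unique())}"
        )
    pooled = (
        records.groupby(["person_id", "hour_index"], as_index=False)[
            ["y_observed", "yhat_nomothetic", "yhat_idiographic"]
        ].mean()
    )
    return pooled


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pooled_correlation(y: np.ndarray, yhat: np.ndarray) -> CorrelationResult:
    """Pearson r between observed and predicted with a Fisher-z 95% CI."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(yhat))
    y, yhat = y[ok], yhat[ok]
    if y.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs for a correlation CI (got {y.size})")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = float(stats.pearsonr(y, yhat).statistic)
    lo, hi = _fisher_ci(r, y.size)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=int(y.size))


def person_correlation(pairs: pd.DataFrame, person_id: str) -> CorrelationResult:
    """Predicted-vs-observed correlation on one person's pairs only."""
    sub = pairs[pairs["person_id"] == person_id]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"person {person_id!r} has {len(sub)} pairs; need >= 3"
        )
    return pooled_correlation(
        sub["y_observed"].to_numpy(), sub["yhat_idiographic"].to_numpy()
    )


def fisher_average(rs: list[float] | np.ndarray) -> tuple[float, tuple[float, float]]:
    """atanh -> mean -> tanh average of correlations, with a t-based CI on
    the z scale (df = k - 1).  |r| = 1 is clamped to 1 - 1e-7 with a warning."""
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise InsufficientDataError("no correlations to average")
    if np.any(np.abs(rs) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(rs) == 1):
        warnings.warn("|r| = 1 clamped to 1 - 1e-7 before Fisher averaging")
        rs = np.clip(rs, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(rs)
    mean_r = float(np.tanh(z.mean()))
    if rs.size < 2:
        return mean_r, (np.nan, np.nan)
    half = stats.t.ppf(0.975, rs.size - 1) * z.std(ddof=1) / np.sqrt(rs.size)
    return mean_r, (float(np.tanh(z.mean() - half)), float(np.tanh(z.mean() + half)))


def summarize_idiographic(
    pooled_pairs: pd.DataFrame, min_pairs: int = 3
) -> IdiographicSummary:
    """Per-person correlations plus their Fisher-z average.

    Persons with undefined correlations (constant observed mood) or fewer
    than `min_pairs` pairs are excluded from the average and listed in
    ``excluded`` with the reason.
    """
    per_person: dict[str, CorrelationResult] = {}
    excluded: dict[str, str] = {}
    for pid in sorted(pooled_pairs["person_id"].unique()):
        try:
            per_person[pid] = person_correlation(pooled_pairs, pid)
        except (InsufficientDataError, UndefinedCorrelationError) as exc:
            excluded[pid] = str(exc)
    if not per_person:
        raise InsufficientDataError("no person had a defined correlation")
    rs = [res.r for res in per_person.values()]
    avg, ci = fisher_average(rs)
    return IdiographicSummary(
        per_person=per_person, average_r=avg, average_ci=ci, excluded=excluded
    )


# ---------------------------------------------------------------------------
# Report writing and figures
# ---------------------------------------------------------------------------

def per_person_table(summary: IdiographicSummary) -> pd.DataFrame:
    rows = [
        dict(person_id=pid, r=res.r, ci_low=res.ci_low, ci_high=res.ci_high, n=res.n)
        for pid, res in summary.per_person.items()
    ]
    return pd.DataFrame(rows, columns=["person_id", "r", "ci_low", "ci_high", "n"])


def write_report(
    outdir: str | Path,
    pooled: CorrelationResult,
    summary: IdiographicSummary,
    extra_lines: list[str] | None = None,
) -> None:
    """Emit the evaluation report as delimited text under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [dict(r=pooled.r, ci_low=pooled.ci_low, ci_high=pooled.ci_high, n=pooled.n)]
    ).to_csv(outdir / "pooled_correlation.csv", index=False)
    per_person_table(summary).to_csv(outdir / "per_person_correlations.csv", index=False)
    lines = [
        f"pooled r = {pooled.r:.3f}, 95% CI [{pooled.ci_low:.3f}, {pooled.ci_high:.3f}], n = {pooled.n}",
        f"Fisher-z average per-person r = {summary.average_r:.3f}, "
        f"95% CI [{summary.average_ci[0]:.3f}, {summary.average_ci[1]:.3f}] "
        f"over {len(summary.per_person)} persons",
    ]
    for pid, reason in summary.excluded.items():
        lines.append(f"excluded {pid}: {reason}")
    lines.extend(extra_lines or [])
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


def plot_forest(summary: IdiographicSummary, path: str | Path) -> None:
    """Forest plot of per-person correlations with the Fisher-z average."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = per_person_table(summary).sort_values("r")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(tbl) + 1.5))
    ypos = np.arange(len(tbl))
    ax.errorbar(
        tbl["r"],
        ypos,
        xerr=[tbl["r"] - tbl["ci_low"], tbl["ci_high"] - tbl["r"]],
        fmt="o",
        color="tab:blue",
        ecolor="gray",
        capsize=2,
    )
    ax.axvline(summary.average_r, linestyle=":", color="black", label="Fisher-z average")
    ax.axvline(0.0, linestyle="-", color="lightgray", zorder=0)
    ax.set_yticks(ypos, tbl["person_id"])
    ax.set_xlabel("predicted-vs-observed r (per person)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(pooled_pairs: pd.DataFrame, path: str | Path, max_persons: int = 12) -> None:
    """Observed vs predicted hourly mood trajectories, one panel per person."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pids = sorted(pooled_pairs["person_id"].unique())[:max_persons]
    ncol = 3
    nrow = int(np.ceil(len(pids) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(11, 2.2 * nrow), squeeze=False, sharex=True)
    for ax, pid in zip(axes.ravel(), pids):
        sub = pooled_pairs[pooled_pairs["person_id"] == pid].sort_values("hour_index")
        ax.plot(sub["hour_index"], sub["y_observed"], color="tab:red", lw=1, label="observed")
        ax.plot(sub["hour_index"], sub["yhat_idiographic"], color="tab:blue", lw=1, label="predicted")
        ax.set_title(pid, fontsize=8)
    for ax in axes.ravel()[len(pids):]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=7)
    fig.supxlabel("hour since cohort start")
    fig.supylabel("depressed mood (0-100)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
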