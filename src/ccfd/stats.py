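"""Statistical comparison of flow-deficit metrics across devices and slabs.

The comparison layer mirrors a complete within-subject design: every eye
is measured on every device and every slab.  It provides

- paired Wilcoxon signed-rank tests between devices (exact by full sign
  enumeration for small samples, normal approximation with tie correction
  otherwise);
- ICC(2,1) — two-way random effects, single measure, absolute agreement
  (Shrout-Fleiss) — with its F-based 95% confidence interval;
- a repeated-measures ANOVA over the condition factor (the balanced
  complete-design equivalent of a mixed model with a random subject
  intercept) with Tukey HSD post-hoc tests on the model's error term;
- table builders producing mean +/- SD summaries with pairwise p-values
  and a slab-by-slab p-value matrix per device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "PairwiseTestResult",
    "ICCResult",
    "RMANOVAResult",
    "MetricMatrix",
    "ComparisonTables",
    "wilcoxon_signed_rank",
    "icc2",
    "repeated_measures_comparison",
    "tukey_posthoc",
    "mixed_factorial_anova",
    "build_comparison_tables",
]

METRIC_COLUMNS = ("fd_percent", "mean_fd_size_um2", "total_fd_area_mm2", "fd_count")


@dataclass(frozen=True)
class PairwiseTestResult:
    condition_a: str
    condition_b: str
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) point estimate with 95% confidence bounds."""

    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1) two-way random, single measure, absolute agreement"

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if not (self.ci_low <= self.icc + 1e-9 and self.icc - 1e-9 <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


@dataclass(frozen=True)
class RMANOVAResult:
    """One-factor repeated-measures ANOVA on an eyes x conditions table."""

    f_condition: float
    p_condition: float
    df_condition: int
    df_error: int
    ms_error: float
    condition_means: dict
    n_subjects: int


@dataclass(frozen=True)
class MetricMatrix:
    """Complete eyes x conditions table of one flow-deficit metric."""

    values: np.ndarray
    eye_ids: tuple
    condition_labels: tuple
    metric_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D eyes x conditions array")
        if v.shape != (len(self.eye_ids), len(self.condition_labels)):
            raise ValueError("values shape does not match the row/column labels")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing or non-finite cells (complete-case design)")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        metric: str,
        condition: str,
        eye: str = "eye_id",
    ) -> "MetricMatrix":
        """Pivot a long-format table into an eyes x conditions matrix."""
        wide = df.pivot_table(index=eye, columns=condition, values=metric,
                              aggfunc="mean", sort=True)
        if wide.isna().any().any():
            missing = [
                (str(i), str(c))
                for i in wide.index for c in wide.columns
                if pd.isna(wide.loc[i, c])
            ]
            raise ValueError(f"incomplete design; missing cells: {missing}")
        return cls(wide.to_numpy(), tuple(wide.index), tuple(wide.columns), metric)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all sign assignments.

    Works on doubled ranks so midranks from ties stay integral; the
    distribution of 2*W+ is built by polynomial convolution over the 2^n
    equally likely sign patterns.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    denom = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / denom
    sf = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    a,
    b,
    condition_a: str = "a",
    condition_b: str = "b",
    exact_max_n: int = 15,
) -> PairwiseTestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention).  With all
    differences zero the test is degenerate and p = 1.  For n <= 15
    non-zero pairs the p-value is exact by full enumeration of the 2^n
    sign assignments (valid under ties, since the enumeration conditions
    on the observed midranks); beyond that the normal approximation with
    tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D paired samples of equal length")
    d = a - b
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return PairwiseTestResult(condition_a, condition_b, 0.0, 1.0, "degenerate")
    if n < 5:
        raise ValueError(
            f"need >= 5 non-zero differences after zero removal, got {n}"
        )
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        res = sps.wilcoxon(nz, zero_method="wilcox", correction=False,
                           alternative="two-sided", method="approx")
        p = float(res.pvalue)
        method = "approx"
    return PairwiseTestResult(condition_a, condition_b, w_plus, p, method)


# ---------------------------------------------------------------------------
# Two-way mean squares (subjects x conditions), shared by ICC and RM-ANOVA

def _two_way_mean_squares(values: np.ndarray):
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc2(matrix: MetricMatrix, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Point estimate per Shrout-Fleiss,
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``,
    with the F-based confidence interval of the two-way random model
    (McGraw-Wong).  Refuses a matrix with zero total variance, where the
    ICC is undefined.
    """
    v = matrix.values
    n, k = v.shape
    if n < 3:
        raise ValueError("need at least 3 subjects (rows)")
    if np.allclose(v, v.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    msr, msc, mse = _two_way_mean_squares(v)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0.0:
        # Perfect within-subject agreement; the interval degenerates.
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))
    # F-based interval for the two-way random model (McGraw-Wong), with
    # Satterthwaite degrees of freedom for the denominator combination.
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (
        (n - 1) * k**2 * icc**2 * fj**2
        + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    )
    v_df = vn / vd
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v_df)
    f_up = sps.f.ppf(1 - alpha / 2, v_df, n - 1)
    ci_low = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    ci_low = float(min(ci_low, icc))
    ci_high = float(max(min(ci_high, 1.0), icc))
    return ICCResult(icc=float(icc), ci_low=ci_low, ci_high=ci_high)


def repeated_measures_comparison(matrix: MetricMatrix) -> RMANOVAResult:
    """Repeated-measures ANOVA over the condition factor.

    Two-way (subjects x conditions) decomposition with the subject as a
    random intercept; under the complete balanced design this is the
    classical repeated-measures ANOVA, with
    ``F = MS_condition / MS_error`` on ``(k-1, (n-1)(k-1))`` degrees of
    freedom.  A zero error mean square is resolved by inspection: the
    condition effect is either exactly null (p = 1) or infinitely strong
    (p = 0).
    """
    v = matrix.values
    n, k = v.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    _, msc, mse = _two_way_mean_squares(v)
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    if mse == 0.0:
        f_stat = np.inf if msc > 0 else 0.0
        p = 0.0 if msc > 0 else 1.0
    else:
        f_stat = msc / mse
        p = float(sps.f.sf(f_stat, df_c, df_e))
    return RMANOVAResult(
        f_condition=float(f_stat),
        p_condition=p,
        df_condition=df_c,
        df_error=df_e,
        ms_error=float(mse),
        condition_means={
            lab: float(m) for lab, m in zip(matrix.condition_labels, v.mean(axis=0))
        },
        n_subjects=n,
    )


def tukey_posthoc(matrix: MetricMatrix) -> list[PairwiseTestResult]:
    """Tukey HSD over all condition pairs on the RM-ANOVA error term.

    Each pair is compared through the studentized-range distribution:
    ``q = |m_i - m_j| / sqrt(MS_error / n)`` referred to the range of
    ``k`` means on ``(n-1)(k-1)`` error degrees of freedom (family-wise
    alpha at the nominal level by construction).
    """
    k = len(matrix.condition_labels)
    if k < 3:
        raise ValueError("Tukey post-hoc needs >= 3 conditions; use the "
                         "paired Wilcoxon path for two")
    res = repeated_measures_comparison(matrix)
    n = res.n_subjects
    se = np.sqrt(res.ms_error / n)
    out = []
    for (la, ma), (lb, mb) in combinations(res.condition_means.items(), 2):
        diff = abs(ma - mb)
        if se == 0.0:
            p = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else np.inf
        else:
            q = diff / se
            p = float(sps.studentized_range.sf(q, k, res.df_error))
        out.append(PairwiseTestResult(str(la), str(lb), float(q),
                                      min(max(p, 0.0), 1.0), "tukey-hsd"))
    return out


def mixed_factorial_anova(
    df: pd.DataFrame,
    metric: str = "fd_percent",
    subject: str = "eye_id",
    within: tuple[str, str] = ("device", "slab"),
) -> pd.DataFrame:
    """Two-way within-subject ANOVA over the device and slab factors.

    Thin wrapper over statsmodels' repeated-measures ANOVA; under the
    complete balanced design this matches the mixed linear model with a
    random subject intercept.  Returns the ANOVA table with F statistics
    and p-values per factor (and their interaction).
    """
    from statsmodels.stats.anova import AnovaRM

    counts = df.groupby([subject, *within], observed=True)[metric].count()
    if (counts != 1).any():
        raise ValueError("design must be complete with one record per cell")
    return AnovaRM(df, metric, subject, within=list(within)).fit().anova_table


# ---------------------------------------------------------------------------
# Table builders

def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


@dataclass(frozen=True)
class ComparisonTables:
    """Summary tables of a device x slab cohort comparison."""

    table1: pd.DataFrame
    table2: dict
    icc: pd.DataFrame

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1_analogue.csv", index=False)
        frames = []
        for device, mat in self.table2.items():
            m = mat.copy()
            m.insert(0, "device", device)
            m.insert(1, "slab", m.index)
            frames.append(m)
        pd.concat(frames).to_csv(out / "table2_analogue.csv", index=False)
        self.icc.to_csv(out / "icc.csv", index=False)


def build_comparison_tables(
    df: pd.DataFrame,
    metrics: tuple = METRIC_COLUMNS,
    fd_metric: str = "fd_percent",
) -> ComparisonTables:
    """Build the device-comparison and slab-comparison summary tables.

    ``df`` is the long per-image metrics table with columns ``eye_id``,
    ``device``, ``slab`` and the metric columns.  Produces:

    - a per-device summary per metric and slab (mean +/- SD at 2 decimals)
      with pairwise device p-values from the paired Wilcoxon test;
    - per device, a slab x slab p-value matrix for ``fd_metric`` from the
      Tukey HSD post-hoc on the repeated-measures model;
    - per device, the ICC(2,1) of ``fd_metric`` across slab columns.

    Refuses an incomplete design, listing the missing cells.
    """
    metrics = [m for m in metrics if m in df.columns]
    if not metrics:
        raise ValueError("no known metric columns found")
    devices = sorted(df["device"].unique())
    slabs = sorted(df["slab"].unique())
    eyes = sorted(df["eye_id"].unique())
    counts = df.groupby(["eye_id", "device", "slab"], observed=True)[metrics[0]].count()
    full = pd.MultiIndex.from_product([eyes, devices, slabs],
                                      names=["eye_id", "device", "slab"])
    missing = full.difference(counts.index)
    if len(missing) or (counts != 1).any():
        raise ValueError(f"incomplete design; missing cells: {list(missing)[:20]}")

    # Table-1 analogue: mean +/- SD per device x slab with device-pair
    # Wilcoxon p-values (the pairwise column reported in the source tables).
    rows = []
    for metric in metrics:
        for slab in slabs:
            sub = df[df["slab"] == slab]
            wide = sub.pivot(index="eye_id", columns="device", values=metric)
            row = {"metric": metric, "slab": slab}
            for dev in devices:
                row[dev] = _mean_sd(wide[dev].to_numpy())
            for da, db in combinations(devices, 2):
                res = wilcoxon_signed_rank(
                    wide[da].to_numpy(), wide[db].to_numpy(), da, db
                )
                row[f"p {da} vs {db}"] = res.p_value
            rows.append(row)
    table1 = pd.DataFrame(rows)

    # Table-2 analogue: slab x slab p-value matrix per device.
    table2 = {}
    icc_rows = []
    for dev in devices:
        sub = df[df["device"] == dev]
        mat = MetricMatrix.from_long(sub, fd_metric, condition="slab")
        pmat = pd.DataFrame(np.nan, index=mat.condition_labels,
                            columns=mat.condition_labels)
        for res in tukey_posthoc(mat):
            pmat.loc[res.condition_a, res.condition_b] = res.p_value
            pmat.loc[res.condition_b, res.condition_a] = res.p_value
        table2[dev] = pmat
        icc_res = icc2(mat)
        icc_rows.append({
            "device": dev, "metric": fd_metric, "icc2": icc_res.icc,
            "ci_low": icc_res.ci_low, "ci_high": icc_res.ci_high,
        })
    return ComparisonTables(table1, table2, pd.DataFrame(icc_rows))
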