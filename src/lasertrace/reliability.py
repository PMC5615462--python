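"""Repeatability and validity statistics for repeated-trial outcome tables.

The core object is a subjects x trials matrix of one outcome (Acuity or
Speed) for one condition (hand x movement direction).  From its two-way
ANOVA decomposition (subjects, trials, residual) this module derives:

* **ICC** — intraclass correlation, two-way random effects, single
  measures, in both the *consistency* and *absolute agreement* forms, with
  95% confidence intervals from the F-distribution method.  The two forms
  are reported side by side because the conventional labels are easy to
  mix: "ICC(2,1)" usually denotes absolute agreement, while "two-way random
  consistency" describes the consistency form.
* **SEM** — standard error of measurement, computed from the standard
  deviation of consecutive-trial difference scores divided by sqrt(2), with
  a chi-square confidence interval on the underlying SD.
* **RM-ANOVA** — one-way repeated-measures F test on the trial factor, the
  screen for systematic bias (learning) across trials.

A single mean-squares decomposition feeds the ICC and the RM-ANOVA, so the
two can never disagree about the underlying variance components.

Usage follows the model/results convention::

    res = TrialReliability.from_dataframe(df, outcome="acuity_pct").fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LaserTraceError


# ---------------------------------------------------------------------------
# shared two-way decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanSquares:
    """Two-way (subjects x trials) mean squares of a complete matrix."""

    msr: float   # between-subjects (rows)
    msc: float   # between-trials (columns)
    mse: float   # residual (interaction)
    n: int
    k: int

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


def _validate_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise LaserTraceError("trial matrix must be 2-D (subjects x trials)")
    if np.isnan(m).any():
        raise LaserTraceError("trial matrix contains missing cells; apply "
                              "listwise deletion first")
    n, k = m.shape
    if n < 2 or k < 2:
        raise LaserTraceError(f"need >= 2 subjects and >= 2 trials, got {n} x {k}")
    return m


def mean_squares(matrix) -> MeanSquares:
    """Two-way ANOVA decomposition of a complete subjects x trials matrix."""
    m = _validate_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return MeanSquares(
        msr=ss_rows / (n - 1),
        msc=ss_cols / (k - 1),
        mse=max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        n=n, k=k,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def icc(matrix, form: str = "consistency", alpha: float = 0.05):
    """Single-measures intraclass correlation with a 95% CI.

    ``form="consistency"``: (MSR - MSE) / (MSR + (k-1) MSE) — trial-to-trial
    rank stability, insensitive to a uniform shift between trials.
    ``form="agreement"``: adds the trial-variance penalty
    k (MSC - MSE) / n to the denominator — absolute agreement.

    Confidence intervals use the F-distribution method appropriate to each
    form (exact for consistency; the Satterthwaite-df approximation for
    agreement).

    Returns ``(value, (ci_low, ci_high))``.
    """
    ms = mean_squares(matrix)
    msr, msc, mse, n, k = ms.msr, ms.msc, ms.mse, ms.n, ms.k
    if msr <= 0 and mse <= 0:
        raise LaserTraceError("zero total variance: ICC undefined")
    if form == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise LaserTraceError("zero variance: ICC undefined")
        value = (msr - mse) / denom
        if mse == 0:
            return 1.0, (1.0, 1.0)
        f_obs = msr / mse
        fu = f_obs * stats.f.ppf(1 - alpha / 2, ms.df_error, ms.df_rows)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, ms.df_rows, ms.df_error)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(value), (float(lo), float(hi))
    if form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise LaserTraceError("zero variance: ICC undefined")
        value = (msr - mse) / denom
        if mse == 0 and msc == 0:
            return 1.0, (1.0, 1.0)
        r = value
        a = k * r / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / ms.df_cols + (b * mse) ** 2 / ms.df_error)
            f1 = stats.f.ppf(1 - alpha / 2, ms.df_rows, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, ms.df_rows)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = 1.0
        return float(value), (float(lo), float(hi))
    raise LaserTraceError(f"unknown ICC form {form!r}")


def consecutive_differences(matrix) -> np.ndarray:
    """Per-subject consecutive-trial differences pooled into one vector.

    For k trials this stacks trial2-trial1, trial3-trial2, ... across all
    subjects: n (k-1) values.
    """
    m = _validate_matrix(matrix)
    return np.diff(m, axis=1).ravel(order="F")


def sem_from_differences(matrix, alpha: float = 0.05, method: str = "pooled"):
    """Standard error of measurement from consecutive-trial differences.

    SEM = SD(differences) / sqrt(2).  With ``method="pooled"`` (default) the
    consecutive-difference sets are pooled into one vector before taking
    the SD; ``method="mean_of_pairs"`` computes one SEM per consecutive
    pair and averages them.  The CI is a chi-square interval on the SD of
    the pooled vector, divided by sqrt(2).

    Returns ``(sem, (ci_low, ci_high))``.
    """
    m = _validate_matrix(matrix)
    diffs = np.diff(m, axis=1)
    if method == "pooled":
        vec = diffs.ravel(order="F")
        sd = float(np.std(vec, ddof=1))
        sem = sd / np.sqrt(2.0)
    elif method == "mean_of_pairs":
        sems = [float(np.std(diffs[:, j], ddof=1)) / np.sqrt(2.0)
                for j in range(diffs.shape[1])]
        sem = float(np.mean(sems))
        vec = diffs.ravel(order="F")
        sd = float(np.std(vec, ddof=1))
    else:
        raise LaserTraceError(f"unknown SEM method {method!r}")
    df = vec.size - 1
    if df < 1:
        raise LaserTraceError("need >= 2 difference values for SEM")
    lo = sd * np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df)) / np.sqrt(2.0)
    hi = sd * np.sqrt(df / stats.chi2.ppf(alpha / 2, df)) / np.sqrt(2.0)
    return sem, (float(lo), float(hi))


def rm_anova(matrix, correction: str | None = None):
    """One-way repeated-measures ANOVA on the trial factor.

    F = MS_trials / MS_error with (k-1, (n-1)(k-1)) degrees of freedom,
    sphericity assumed.  ``correction="gg"`` applies the Greenhouse-Geisser
    epsilon to the degrees of freedom (off by default).  A zero residual
    mean square with a nonzero trial effect yields ``F = inf, p = 0`` — a
    perfect systematic effect.

    Returns ``(F, p)``.
    """
    ms = mean_squares(matrix)
    if ms.mse == 0:
        if ms.msc == 0:
            raise LaserTraceError("degenerate matrix: no trial or residual variance")
        return float("inf"), 0.0
    f_obs = ms.msc / ms.mse
    df1, df2 = float(ms.df_cols), float(ms.df_error)
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(np.asarray(matrix, dtype=float))
        df1 *= eps
        df2 *= eps
    elif correction is not None:
        raise LaserTraceError(f"unknown correction {correction!r}")
    p = float(stats.f.sf(f_obs, df1, df2))
    return float(f_obs), p


def _greenhouse_geisser_epsilon(m: np.ndarray) -> float:
    k = m.shape[1]
    s = np.cov(m, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum()
                     + k ** 2 * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def speed_accuracy_correlation(acuity, speed):
    """Spearman rank correlation between Acuity and Speed.

    Mid-ranks for ties, Pearson on the ranks, p from the t approximation.
    Returns ``(rho, p)``.
    """
    a = np.asarray(acuity, dtype=float)
    s = np.asarray(speed, dtype=float)
    if a.shape != s.shape or a.ndim != 1:
        raise LaserTraceError("acuity and speed must be paired 1-D vectors")
    if a.size < 4:
        raise LaserTraceError("need n >= 4 pairs for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(s) == 0:
        raise LaserTraceError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(a, s)
    return float(rho), float(p)


@dataclass(frozen=True)
class GroupComparison:
    mean_diff: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    paired: bool
    degenerate: bool = False


def compare_groups(a, b, paired: bool = False, alpha: float = 0.05) -> GroupComparison:
    """t-test comparison of two outcome vectors.

    Paired t for within-subject contrasts (equal lengths required); Welch's
    independent t otherwise.  A paired contrast whose differences have zero
    variance is flagged degenerate rather than reported with a spurious
    statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise LaserTraceError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise LaserTraceError("paired comparison requires equal lengths")
        diffs = a - b
        mean_diff = float(diffs.mean())
        if np.ptp(diffs) == 0:
            t = 0.0 if mean_diff == 0 else float("inf") * np.sign(mean_diff)
            return GroupComparison(mean_diff, float(t), 0.0 if mean_diff else 1.0,
                                   mean_diff, mean_diff, paired=True, degenerate=True)
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        mean_diff = float(a.mean() - b.mean())
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return GroupComparison(mean_diff, float(res.statistic), float(res.pvalue),
                           float(ci.low), float(ci.high), paired=paired)


def normality_gate(values):
    """Shapiro-Wilk normality screen used to pick parametric vs rank tests.

    Returns ``(W, p)``.  Valid for 3 <= n <= 5000; constant samples are
    rejected as undefined.
    """
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise LaserTraceError(f"Shapiro-Wilk defined for 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise LaserTraceError("constant sample: normality test undefined")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class TrialReliability:
    """Repeatability model for one outcome over repeated trials.

    Parameters
    ----------
    matrix : (n_subjects, k_trials) array
        Complete outcome table for one condition.
    condition : str, optional
        Label (e.g. ``"right/dorsal"``) carried into the results.
    outcome : str
        Outcome name for reporting (default ``"acuity_pct"``).
    n_dropped : int
        Subjects removed by listwise deletion before the matrix was built.
    """

    def __init__(self, matrix, condition: str | None = None,
                 outcome: str = "acuity_pct", n_dropped: int = 0):
        self.matrix = _validate_matrix(matrix)
        self.condition = condition
        self.outcome = outcome
        self.n_dropped = int(n_dropped)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "acuity_pct",
                       subject: str = "participant", trial: str = "trial",
                       condition: str | None = None, where: dict | None = None
                       ) -> "TrialReliability":
        """Build the subjects x trials matrix from a tidy trial table.

        ``where`` filters rows by column equality (e.g. ``{"hand": "right",
        "anatomical_direction": "dorsal"}``).  Subjects missing any trial
        are removed listwise and counted in ``n_dropped``.
        """
        sub = df
        if where:
            for col, val in where.items():
                sub = sub[sub[col] == val]
        wide = sub.pivot_table(index=subject, columns=trial, values=outcome,
                               aggfunc="mean")
        complete = wide.dropna()
        return cls(complete.to_numpy(), condition=condition, outcome=outcome,
                   n_dropped=len(wide) - len(complete))

    def fit(self, alpha: float = 0.05, sem_method: str = "pooled") -> "ReliabilityResults":
        ms = mean_squares(self.matrix)
        icc_c, ci_c = icc(self.matrix, form="consistency", alpha=alpha)
        icc_a, ci_a = icc(self.matrix, form="agreement", alpha=alpha)
        sem, sem_ci = sem_from_differences(self.matrix, alpha=alpha, method=sem_method)
        f_obs, p = rm_anova(self.matrix)
        return ReliabilityResults(
            model=self, mean_squares_=ms,
            icc_consistency=icc_c, icc_consistency_ci=ci_c,
            icc_agreement=icc_a, icc_agreement_ci=ci_a,
            sem=sem, sem_ci=sem_ci, anova_F=f_obs, anova_p=p,
            trial_means=self.matrix.mean(axis=0),
            trial_sds=self.matrix.std(axis=0, ddof=1),
            alpha=alpha,
        )


@dataclass
class ReliabilityResults:
    """Fitted repeatability estimates for one condition's trial matrix."""

    model: TrialReliability
    mean_squares_: MeanSquares
    icc_consistency: float
    icc_consistency_ci: tuple[float, float]
    icc_agreement: float
    icc_agreement_ci: tuple[float, float]
    sem: float
    sem_ci: tuple[float, float]
    anova_F: float
    anova_p: float
    trial_means: np.ndarray
    trial_sds: np.ndarray
    alpha: float = 0.05

    @property
    def n_subjects(self) -> int:
        return self.mean_squares_.n

    @property
    def k_trials(self) -> int:
        return self.mean_squares_.k

    def to_dict(self) -> dict:
        return {
            "condition": self.model.condition,
            "outcome": self.model.outcome,
            "n_subjects": self.n_subjects,
            "k_trials": self.k_trials,
            "n_dropped": self.model.n_dropped,
            "icc_consistency": self.icc_consistency,
            "icc_consistency_ci95": list(self.icc_consistency_ci),
            "icc_agreement": self.icc_agreement,
            "icc_agreement_ci95": list(self.icc_agreement_ci),
            "sem": self.sem,
            "sem_ci95": list(self.sem_ci),
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "trial_means": self.trial_means.tolist(),
            "trial_sds": self.trial_sds.tolist(),
        }

    def summary(self) -> str:
        """Human-readable repeatability table for this condition."""
        lines = []
        cond = f" [{self.model.condition}]" if self.model.condition else ""
        lines.append(f"Repeatability of {self.model.outcome}{cond}")
        lines.append(f"  subjects: {self.n_subjects}  trials: {self.k_trials}"
                     f"  dropped (incomplete): {self.model.n_dropped}")
        per_trial = "  ".join(
            f"T{j + 1} {m:.1f} ({s:.1f})"
            for j, (m, s) in enumerate(zip(self.trial_means, self.trial_sds)))
        lines.append(f"  trial mean (SD): {per_trial}")
        pct = int(round((1 - self.alpha) * 100))
        lines.append(
            f"  ICC consistency: {self.icc_consistency:.2f} "
            f"({pct}% CI {self.icc_consistency_ci[0]:.2f}-{self.icc_consistency_ci[1]:.2f})")
        lines.append(
            f"  ICC agreement:   {self.icc_agreement:.2f} "
            f"({pct}% CI {self.icc_agreement_ci[0]:.2f}-{self.icc_agreement_ci[1]:.2f})")
        lines.append(
            f"  SEM: {self.sem:.2f} ({pct}% CI {self.sem_ci[0]:.2f}-{self.sem_ci[1]:.2f})")
        lines.append(
            f"  RM-ANOVA (trial factor): F = {self.anova_F:.2f}, p = {self.anova_p:.4g}")
        return "\n".join(lines)


def reliability_by_condition(df: pd.DataFrame, outcome: str = "acuity_pct",
                             by=("hand", "anatomical_direction")) -> dict:
    """Fit :class:`TrialReliability` per condition of a tidy trial table."""
    out = {}
    for keys, _sub in df.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = "/".join(str(k) for k in keys)
        model = TrialReliability.from_dataframe(
            df, outcome=outcome, condition=label,
            where=dict(zip(by, keys)))
        out[label] = model.fit()
    return out
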