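"""Inter-device agreement statistics.

Subjects are lesions, "methods" are the PACS reference plus the device
captures.  Four tools: the one-way random-effects intraclass correlation
ICC(1) with its exact F-based 95% CI, the Friedman rank test (with
mid-ranks and tie correction, plus an exact permutation p-value for tiny
tables), Kendall's W as the post-hoc effect size W = chi2 / (n (k-1)), and
Bland-Altman bias / limits-of-agreement against an a-priori critical
difference.  A uniform-draw presentation randomizer reproduces the
randomized reading order used for the raters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AgreementError(ValueError):
    """Raised for incomplete tables or undefined statistics."""


@dataclass
class RatingTable:
    """n_subjects × k_methods matrix of one measure across methods."""

    values: np.ndarray
    measure_name: str
    method_names: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AgreementError("rating table must be 2-D (subjects × methods)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise AgreementError("need n >= 2 subjects and k >= 2 methods")
        if np.isnan(self.values).any():
            raise AgreementError("rating table has missing cells")
        if not self.method_names:
            self.method_names = [f"method_{j}" for j in range(k)]
        if not self.subject_ids:
            self.subject_ids = [f"subject_{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.method_names
        ).to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path: str | Path, measure_name: str) -> "RatingTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            measure_name=measure_name,
            method_names=[str(c) for c in df.columns],
            subject_ids=[str(i) for i in df.index],
        )


# ---------------------------------------------------------------------------
# ICC(1)
# ---------------------------------------------------------------------------


def icc1(
    table: RatingTable | np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """One-way random-effects ICC(1) with an exact F-based CI.

    From the one-way ANOVA of subjects, ICC = (MSB − MSW) / (MSB +
    (k−1)·MSW): the share of total variance attributable to true
    between-subject differences.  The CI inverts the F distribution of
    MSB/MSW with (n−1, n(k−1)) degrees of freedom.
    """
    values = table.values if isinstance(table, RatingTable) else np.asarray(table, float)
    n, k = values.shape
    grand = values.mean()
    subject_means = values.mean(axis=1)
    ssb = k * ((subject_means - grand) ** 2).sum()
    ssw = ((values - subject_means[:, None]) ** 2).sum()
    df_b, df_w = n - 1, n * (k - 1)
    msb = ssb / df_b
    msw = ssw / df_w
    if msb == 0 and msw == 0:
        raise AgreementError("zero total variance: ICC undefined")
    if msw == 0:
        return 1.0, (1.0, 1.0)
    f_obs = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_upper = stats.f.ppf(1 - alpha / 2, df_b, df_w)
    f_lower = stats.f.ppf(1 - alpha / 2, df_w, df_b)
    fl = f_obs / f_upper
    fu = f_obs * f_lower
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Friedman test and Kendall's W
# ---------------------------------------------------------------------------


def _friedman_chi2(values: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from within-subject mid-ranks."""
    n, k = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    col_sums = ranks.sum(axis=0)
    numerator = 12.0 * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denominator = n * k * (k + 1) - ties / (k - 1)
    if denominator <= 0:  # every row fully tied: no information, no effect
        return 0.0
    return float(numerator / denominator)


def friedman(
    table: RatingTable | np.ndarray, exact: bool = False
) -> tuple[float, float]:
    """Friedman rank test across methods; returns (chi2, p).

    Mid-ranks handle ties, with the standard tie-correction in the
    denominator.  With ``exact=True`` (available for n·k ≤ 12) the p-value
    is computed by exhaustive enumeration of all within-subject rank
    permutations instead of the chi-square approximation.
    """
    values = table.values if isinstance(table, RatingTable) else np.asarray(table, float)
    n, k = values.shape
    if k < 2:
        raise AgreementError("need k >= 2 methods")
    chi2 = _friedman_chi2(values)
    if exact:
        if n * k > 12:
            raise AgreementError("exact permutation p only offered for n*k <= 12")
        p = _friedman_exact_p(values, chi2)
    else:
        p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return chi2, p


def _friedman_exact_p(values: np.ndarray, chi2_obs: float) -> float:
    """P(chi2 >= observed) under uniform within-subject rank permutations."""
    n, k = values.shape
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = len(perms) ** n
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.stack([values[i, list(p)] for i, p in enumerate(assignment)])
        if _friedman_chi2(permuted) >= chi2_obs - 1e-12:
            count += 1
    return count / total


def kendall_w(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance: W = chi2 / (n (k-1)), in [0,1]."""
    if chi2 < 0:
        raise AgreementError("chi2 must be >= 0")
    if n < 1 or k < 2:
        raise AgreementError("need n >= 1 and k >= 2")
    return float(np.clip(chi2 / (n * (k - 1)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    within_critical: bool
    critical_difference: float


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    critical_difference: float,
) -> BlandAltman:
    """Agreement of method ``y`` against reference ``x``.

    bias = mean(y − x); limits of agreement = bias ± 1.96 SD(y − x);
    ``within_critical`` is True when every per-subject difference is
    strictly smaller in magnitude than the a-priori critical difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise AgreementError("need at least 2 subjects")
    if not critical_difference > 0:
        raise AgreementError("critical_difference must be > 0")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        within_critical=bool(np.all(np.abs(diff) < critical_difference)),
        critical_difference=float(critical_difference),
    )


def bland_altman_plot(
    x: Sequence[float],
    y: Sequence[float],
    critical_difference: float,
    path: str | Path,
    title: str = "",
) -> Path:
    """Write a Bland–Altman scatter (mean vs difference) with LoA and the
    critical-difference band as dashed lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ba = bland_altman(x, y, critical_difference)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, y - x, s=25)
    ax.axhline(ba.bias, color="k", lw=1)
    ax.axhline(ba.loa_low, color="k", lw=1, ls=":")
    ax.axhline(ba.loa_high, color="k", lw=1, ls=":")
    ax.axhline(critical_difference, color="gray", lw=1, ls="--")
    ax.axhline(-critical_difference, color="gray", lw=1, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (method − reference)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# randomized presentation order
# ---------------------------------------------------------------------------


def randomize_order(ids: Sequence, seed: int) -> list:
    """Assign each id a uniform [0,1) draw and return ids in ascending draw
    order (ties broken by original index).  Deterministic per seed."""
    ids = list(ids)
    if not ids:
        raise AgreementError("ids must be nonempty")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(ids))
    order = sorted(range(len(ids)), key=lambda i: (draws[i], i))
    return [ids[i] for i in order]


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """All agreement statistics for one measure."""

    measure_name: str
    icc: float
    icc_ci: tuple[float, float]
    friedman_chi2: float
    friedman_p: float
    kendall_w: float
    bland_altman: dict[str, BlandAltman]

    def to_dict(self) -> dict:
        return {
            "measure": self.measure_name,
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "friedman_chi2": self.friedman_chi2,
            "friedman_p": self.friedman_p,
            "kendall_w": self.kendall_w,
            "bland_altman": {
                name: {
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "within_critical": ba.within_critical,
                    "critical_difference": ba.critical_difference,
                }
                for name, ba in self.bland_altman.items()
            },
        }


def analyze_table(
    table: RatingTable,
    critical_difference: float | None,
    reference_method: str | None = None,
) -> AgreementReport:
    """ICC(1), Friedman/Kendall, and per-method Bland–Altman against the
    reference column (defaults to the first method).  Passing
    ``critical_difference=None`` skips the Bland–Altman stage (for ordinal
    or quality measures that are compared by rank tests only)."""
    icc, ci = icc1(table)
    chi2, p = friedman(table)
    w = kendall_w(chi2, table.n, table.k)
    ref = reference_method or table.method_names[0]
    ref_idx = table.method_names.index(ref)
    ba = {}
    if critical_difference is not None:
        for j, name in enumerate(table.method_names):
            if j == ref_idx:
                continue
            ba[name] = bland_altman(
                table.values[:, ref_idx], table.values[:, j], critical_difference
            )
    return AgreementReport(
        measure_name=table.measure_name,
        icc=icc,
        icc_ci=ci,
        friedman_chi2=chi2,
        friedman_p=p,
        kendall_w=w,
        bland_altman=ba,
    )


def write_report(reports: Sequence[AgreementReport], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps({r.measure_name: r.to_dict() for r in reports}, indent=2)
    )
    return path
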