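"""Method-comparison statistics: correlation and Bland-Altman agreement.

Two measurements of the same quantity (e.g. effective forward
transvalvular flow vs aortic flow) are compared with Pearson's r or
Spearman's rho, and with Bland-Altman analysis: mean difference, SD of
differences (n-1 denominator), and 95% limits of agreement at
mean +/- 1.96 SD (no small-sample t correction, following the standard
form of the method).  The paired p-value for the mean difference comes
from a two-sided one-sample t test on the differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    """Correlation and Bland-Altman statistics for paired measurements."""

    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    pearson_r: float | None = None
    spearman_rho: float | None = None
    p_values: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Product-moment or rank correlation with a two-sided p-value.

    Spearman ties are handled by average ranks (the scipy default).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of paired measurements, differences x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    p_values: dict[str, float] = {}
    if sd > 0:
        p_values["mean_difference"] = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p_values["mean_difference"] = 1.0 if mean == 0 else 0.0

    pearson_r = spearman_rho = None
    if n >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        pearson_r, p_pearson = correlation(x, y, "pearson")
        spearman_rho, p_spearman = correlation(x, y, "spearman")
        p_values["pearson"] = p_pearson
        p_values["spearman"] = p_spearman

    return AgreementResult(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        loa_lower=mean - LOA_MULTIPLIER * sd,
        loa_upper=mean + LOA_MULTIPLIER * sd,
        pearson_r=pearson_r,
        spearman_rho=spearman_rho,
        p_values=p_values,
    )


def bland_altman_plot(x, y, path: str | Path, labels=("method A", "method B")) -> None:
    """Scatter and Bland-Altman panels saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    res = bland_altman(x, y)
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 4))
    ax0.scatter(x, y, s=18)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax0.plot(lims, lims, "k--", lw=0.8)
    ax0.set_xlabel(labels[0])
    ax0.set_ylabel(labels[1])
    ax1.scatter((x + y) / 2, x - y, s=18)
    for v, style in ((res.mean_difference, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax1.axhline(v, color="k", ls=style, lw=0.8)
    ax1.set_xlabel("mean of methods")
    ax1.set_ylabel(f"{labels[0]} - {labels[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
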