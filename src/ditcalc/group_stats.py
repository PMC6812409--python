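"""Group comparisons: Levene gate, Tukey HSD or Games–Howell, mean ± SEM.

The comparison procedure mirrors standard metabolic-phenotyping practice:
first a Levene test of homogeneity of variances at the same alpha as the
significance level; if variances are homogeneous, pairwise Tukey HSD
(Tukey–Kramer for unequal group sizes, pooled within-group variance);
otherwise Games–Howell (Welch-type pairwise standard errors with
Welch–Satterthwaite degrees of freedom, studentized-range p-values).
Summaries are reported as mean ± SEM with SEM = sd/sqrt(n) (sample sd,
n − 1 denominator).

Levene is centered on the group mean by default (the classic test and the
SPSS default); ``center="median"`` gives the Brown–Forsythe variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import CalorimetryError

__all__ = [
    "GroupData",
    "PairwiseRecord",
    "ComparisonReport",
    "levene_test",
    "tukey_hsd",
    "games_howell",
    "compare_groups",
]


@dataclass
class GroupData:
    """Labeled per-animal scalar outcomes, one array per group."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise CalorimetryError("need at least 2 groups")
        for label, values in self.groups.items():
            if len(values) < 2:
                raise CalorimetryError(
                    f"group {label!r} has {len(values)} value(s); need >= 2"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    def arrays(self) -> list[np.ndarray]:
        return list(self.groups.values())

    def means_sems(self) -> dict[str, tuple[float, float]]:
        return {
            label: (float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))))
            for label, v in self.groups.items()
        }


@dataclass(frozen=True)
class PairwiseRecord:
    pair: tuple[str, str]
    statistic: float
    pvalue: float
    significant: bool


@dataclass
class ComparisonReport:
    levene_stat: float
    levene_p: float
    chosen_test: str  # "tukey_hsd" | "games_howell"
    alpha: float
    pairwise: list[PairwiseRecord]
    means_sems: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "levene": {"statistic": self.levene_stat, "pvalue": self.levene_p},
            "chosen_test": self.chosen_test,
            "alpha": self.alpha,
            "pairwise": [
                {
                    "pair": list(r.pair),
                    "statistic": r.statistic,
                    "pvalue": r.pvalue,
                    "significant": r.significant,
                }
                for r in self.pairwise
            ],
            "groups": {
                label: {"mean": m, "sem": s}
                for label, (m, s) in self.means_sems.items()
            },
        }


def levene_test(groups: GroupData, center: str = "mean") -> tuple[float, float]:
    """Levene's W for homogeneity of variances; p from F(k-1, N-k)."""
    if center not in ("mean", "median"):
        raise CalorimetryError("center must be 'mean' or 'median'")
    stat, p = stats.levene(*groups.arrays(), center=center)
    return float(stat), float(p)


def tukey_hsd(groups: GroupData, alpha: float = 0.05) -> list[PairwiseRecord]:
    """All-pairs Tukey HSD (Tukey–Kramer for unequal n)."""
    res = stats.tukey_hsd(*groups.arrays())
    labels = groups.labels
    records = []
    for i, j in itertools.combinations(range(groups.k), 2):
        p = float(res.pvalue[i, j])
        records.append(
            PairwiseRecord(
                pair=(labels[i], labels[j]),
                statistic=float(res.statistic[i, j]),
                pvalue=p,
                significant=p < alpha,
            )
        )
    return records


def games_howell(groups: GroupData, alpha: float = 0.05) -> list[PairwiseRecord]:
    """All-pairs Games–Howell comparisons for unequal variances.

    For groups i, j with means m, variances s², sizes n:

        se²  = s_i²/n_i + s_j²/n_j
        q    = |m_i − m_j| / se * sqrt(2)
        df   = se⁴ / [ (s_i²/n_i)²/(n_i−1) + (s_j²/n_j)²/(n_j−1) ]

    and p is the studentized-range upper tail at (q, k, df).
    """
    labels = groups.labels
    arrays = groups.arrays()
    k = groups.k
    means = [a.mean() for a in arrays]
    variances = [a.var(ddof=1) for a in arrays]
    ns = [len(a) for a in arrays]
    records = []
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = variances[i] / ns[i], variances[j] / ns[j]
        se2 = vi + vj
        if se2 == 0:
            diff = abs(means[i] - means[j])
            q, p = (np.inf, 0.0) if diff > 0 else (0.0, 1.0)
        else:
            q = abs(means[i] - means[j]) / np.sqrt(se2) * np.sqrt(2.0)
            df = se2**2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            p = float(stats.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        records.append(
            PairwiseRecord(
                pair=(labels[i], labels[j]),
                statistic=float(q),
                pvalue=p,
                significant=p < alpha,
            )
        )
    return records


def compare_groups(
    groups: GroupData, alpha: float = 0.05, center: str = "mean"
) -> ComparisonReport:
    """Levene-gated post-hoc comparison with mean ± SEM summaries.

    Homogeneous variances (Levene p >= alpha) route to Tukey HSD,
    heterogeneous to Games–Howell.  The gate uses the same alpha as the
    pairwise significance calls.
    """
    stat, p = levene_test(groups, center=center)
    if p >= alpha:
        chosen, pairwise = "tukey_hsd", tukey_hsd(groups, alpha)
    else:
        chosen, pairwise = "games_howell", games_howell(groups, alpha)
    return ComparisonReport(
        levene_stat=stat,
        levene_p=p,
        chosen_test=chosen,
        alpha=alpha,
        pairwise=pairwise,
        means_sems=groups.means_sems(),
    )
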