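"""Preference / performance-index estimators and the group-comparison workflow.

In the reciprocal-conditioning design, two groups of ~30 larvae are
trained with opposite odor/reinforcer pairings.  After training, larvae
distribute over the two odor sides and a neutral zone of the test plate;
a preference score (PREF) per group and one associative performance
index (PI) per reciprocal pair are computed:

    PREF(Odor1/Odor2+) = (#Odor2 - #Odor1) / #Total
    PREF(Odor1+/Odor2) = (#Odor1 - #Odor2) / #Total
    PI = (PREF(Odor1/Odor2+) + PREF(Odor1+/Odor2)) / 2

Negative PI indicates aversive memory, positive appetitive; averaging
the reciprocal PREFs cancels non-associative odor biases, and division
by 2 keeps PI in [-1, 1].  #Total includes neutral-zone and lid larvae.

Group statistics follow a Shapiro-Wilk-gated decision rule: if every
group is compatible with normality at alpha the parametric branch is
used (unpaired t-test for two groups, one-way ANOVA with Tukey's post
hoc for more), otherwise the nonparametric branch (Mann-Whitney, or
Kruskal-Wallis with Dunn's multiple comparisons).  Each group is also
tested against chance level 0 (one-sample t-test or Wilcoxon
signed-rank, by the same normality gate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class BehaviorError(ValueError):
    """Raised on invalid plate counts or group layouts."""


@dataclass(frozen=True)
class PlateCount:
    """Larvae counted on the two sides and the neutral zone of one plate."""

    n_side1: int
    n_side2: int
    n_neutral: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_side1, self.n_side2, self.n_neutral):
            if int(v) != v or v < 0:
                raise BehaviorError(f"counts must be nonnegative integers, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_side1 + self.n_side2 + self.n_neutral


@dataclass(frozen=True)
class ReciprocalPair:
    """Plate counts from the two reciprocally trained groups.

    ``count_O1_O2plus`` comes from the group trained with Odor2
    reinforced, ``count_O1plus_O2`` from the group trained with Odor1
    reinforced; odor1 is mapped to side1 and odor2 to side2 on both.
    """

    count_O1_O2plus: PlateCount
    count_O1plus_O2: PlateCount


def _checked_total(total: int) -> int:
    if total < 1:
        raise BehaviorError("preference undefined for an empty plate (total = 0)")
    return total


def pref_reciprocal(count: PlateCount, trained: str) -> float:
    """PREF for one reciprocally trained group.

    ``trained`` names the reinforced odor: "odor2" for the Odor1/Odor2+
    group, "odor1" for the Odor1+/Odor2 group.
    """
    total = _checked_total(count.total)
    if trained == "odor2":
        return (count.n_side2 - count.n_side1) / total
    if trained == "odor1":
        return (count.n_side1 - count.n_side2) / total
    raise BehaviorError(f"trained must be 'odor1' or 'odor2', got {trained!r}")


def performance_index(pair: ReciprocalPair) -> float:
    """Associative performance index of one reciprocal experiment pair."""
    p1 = pref_reciprocal(pair.count_O1_O2plus, trained="odor2")
    p2 = pref_reciprocal(pair.count_O1plus_O2, trained="odor1")
    return (p1 + p2) / 2.0


def pref_single_odor(n_odor: int, n_empty: int, n_neutral: int = 0) -> float:
    """Innate odor preference: (#Odor - #Empty) / #Total.

    Positive values indicate attraction to the odor.
    """
    count = PlateCount(n_odor, n_empty, n_neutral)
    return (n_odor - n_empty) / _checked_total(count.total)


def pref_gustatory(n_nacl: int, n_agarose: int, n_neutral: int = 0) -> float:
    """Gustatory preference for NaCl: (#NaCl - #Agarose) / #Total.

    Negative values indicate aversion to sodium chloride.
    """
    count = PlateCount(n_nacl, n_agarose, n_neutral)
    return (n_nacl - n_agarose) / _checked_total(count.total)


# ---------------------------------------------------------------------------
# group statistics


@dataclass(frozen=True)
class PairwiseResult:
    group1: str
    group2: str
    p_value: float
    p_adjusted: float | None = None  # Bonferroni, Dunn branch only


@dataclass(frozen=True)
class OneSampleResult:
    group: str
    test: str  # "one_sample_t" | "wilcoxon"
    p_value: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    shapiro_p: dict[str, float]
    branch: str  # t_test | anova_tukey | mann_whitney | kruskal_dunn
    omnibus_p: float | None
    pairwise: tuple[PairwiseResult, ...]
    vs_zero: tuple[OneSampleResult, ...]
    alpha: float


def dunn_test(
    samples: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> list[PairwiseResult]:
    """Dunn's multiple-comparisons test on rank sums with tie correction.

    For groups i, j with mean pooled ranks R_i, R_j,

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided
    p-values from the standard normal.  An unadjusted and a
    Bonferroni-adjusted p are reported per pair.
    """
    labels = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        n = len(samples[g])
        mean_rank[g] = float(np.mean(ranks[start:start + n]))
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(samples[g1]) + 1.0 / len(samples[g2])))
        if se == 0:
            p = 1.0
        else:
            z = (mean_rank[g1] - mean_rank[g2]) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            PairwiseResult(g1, g2, p_value=p, p_adjusted=min(1.0, p * n_pairs))
        )
    return results


def test_vs_zero(
    replicates: np.ndarray | list[float],
    normality_p: float | None = None,
    alpha: float = 0.05,
    group: str = "",
) -> OneSampleResult:
    """Test one group of scores against chance level 0.

    Uses a one-sample t-test when the group passes Shapiro-Wilk at
    ``alpha`` (normality_p computed here if not supplied), otherwise the
    Wilcoxon signed-rank test.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 3:
        raise BehaviorError("at least 3 replicates required to test against zero")
    if normality_p is None:
        normality_p = _shapiro_p(x)
    if normality_p > alpha:
        if np.ptp(x) == 0 and x[0] != 0:
            raise BehaviorError(
                "constant nonzero replicates: one-sample t-test undefined (zero variance)"
            )
        p = float(stats.ttest_1samp(x, 0.0).pvalue)
        name = "one_sample_t"
    else:
        if np.all(x == 0):
            logger.warning("all replicates zero: Wilcoxon degenerate, reporting p = 1")
            p = 1.0
        else:
            p = float(stats.wilcoxon(x).pvalue)
        name = "wilcoxon"
    return OneSampleResult(group=group, test=name, p_value=p, significant=p < alpha)


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        # constant sample: Shapiro-Wilk undefined; treat as non-normal
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def compare_groups(
    groups: dict[str, np.ndarray | list[float]], alpha: float = 0.05
) -> GroupComparison:
    """Compare PI replicates across groups with the normality-gated workflow.

    All groups pass Shapiro-Wilk at ``alpha`` -> parametric branch
    (unpaired t-test for 2 groups; one-way ANOVA with Tukey's post hoc
    for more); any failure -> nonparametric branch (Mann-Whitney for 2;
    Kruskal-Wallis with Dunn's test for more).  Every group is also
    tested against chance level 0.
    """
    if len(groups) < 2:
        raise BehaviorError("at least 2 groups required")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, x in data.items():
        if x.size < 3:
            raise BehaviorError(f"group {g!r} has fewer than 3 replicates")
    labels = tuple(data)
    shapiro_p = {g: _shapiro_p(x) for g, x in data.items()}
    parametric = all(p > alpha for p in shapiro_p.values())

    omnibus_p: float | None = None
    pairwise: list[PairwiseResult] = []
    if len(data) == 2:
        g1, g2 = labels
        if parametric:
            branch = "t_test"
            p = float(stats.ttest_ind(data[g1], data[g2]).pvalue)
        else:
            branch = "mann_whitney"
            p = float(stats.mannwhitneyu(data[g1], data[g2]).pvalue)
        if np.isnan(p):  # identical constant samples
            p = 1.0
        pairwise.append(PairwiseResult(g1, g2, p_value=p))
    else:
        arrays = [data[g] for g in labels]
        if parametric:
            branch = "anova_tukey"
            omnibus_p = float(stats.f_oneway(*arrays).pvalue)
            tk = stats.tukey_hsd(*arrays)
            for a, b in combinations(range(len(labels)), 2):
                pairwise.append(
                    PairwiseResult(labels[a], labels[b],
                                   p_value=float(tk.pvalue[a, b]))
                )
        else:
            branch = "kruskal_dunn"
            omnibus_p = float(stats.kruskal(*arrays).pvalue)
            pairwise = dunn_test(data)

    vs_zero = tuple(
        test_vs_zero(x, normality_p=shapiro_p[g], alpha=alpha, group=g)
        for g, x in data.items()
    )
    return GroupComparison(
        groups=labels,
        shapiro_p=shapiro_p,
        branch=branch,
        omnibus_p=omnibus_p,
        pairwise=tuple(pairwise),
        vs_zero=vs_zero,
        alpha=alpha,
    )


def significance_code(p: float, alpha: float = 0.05) -> str:
    """'*' for p < alpha, 'n.s.' otherwise (no graded asterisks)."""
    return "*" if p < alpha else "n.s."
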