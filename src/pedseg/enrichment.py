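"""Gene-set overrepresentation and effect-size comparisons.

The prioritized gene list is tested against curated gene sets (e.g. genes
with a central-nervous-system phenotype in a Mendelian-disease catalogue,
or a synaptic-gene inventory) by Fisher's exact test on the 2x2 table

    a = prioritized genes in the set        b = prioritized genes outside
    c = set genes not prioritized           d = rest of the coding universe

with the universe defaulting to 20,203 protein-coding genes. A
multi-category specificity scan Bonferroni-corrects across the sets
tested; two odds ratios are compared on the log scale with standard
errors recovered from their Wald confidence intervals; gene-level score
comparisons (conservation, constraint) use Welch's unequal-variance t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_UNIVERSE_SIZE",
    "EnrichmentResult",
    "OrComparison",
    "fisher_overrepresentation",
    "specificity_scan",
    "compare_log_or",
    "welch_t",
]

DEFAULT_UNIVERSE_SIZE = 20203

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class EnrichmentResult:
    """2x2 overrepresentation test result for one gene set."""

    gene_set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    p_corrected: float | None = None
    significant: bool | None = None

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))

    @property
    def log_or_se(self) -> float:
        """Wald standard error of log OR (defined only for all-positive cells)."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return math.nan
        return math.sqrt(1 / self.a + 1 / self.b + 1 / self.c + 1 / self.d)


@dataclass
class OrComparison:
    """z comparison of two log odds ratios."""

    log_or_1: float
    log_or_2: float
    se_1: float
    se_2: float
    z: float
    p_one_tailed: float


def fisher_overrepresentation(
    hits: int,
    list_size: int,
    set_size: int,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    gene_set_name: str = "",
    conditional_mle: bool = False,
) -> EnrichmentResult:
    """Fisher's exact test of a prioritized gene list against a gene set.

    Parameters
    ----------
    hits
        Prioritized genes that are members of the set.
    list_size
        Total prioritized genes.
    set_size
        Size of the gene set within the universe.
    universe_size
        Number of coding genes the comparison is drawn from.
    conditional_mle
        Report the conditional maximum-likelihood odds ratio (the value
        exact-test software prints) instead of the sample odds ratio
        (a*d)/(b*c). The sample OR is the default.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (minimum-likelihood rule). The 95% CI is Wald on log OR.
    """
    if not (0 <= hits <= list_size <= universe_size):
        raise ValueError("require 0 <= hits <= list_size <= universe_size")
    if hits > set_size or set_size > universe_size:
        raise ValueError("require hits <= set_size <= universe_size")
    a = hits
    b = list_size - hits
    c = set_size - hits
    d = universe_size - list_size - c
    if d < 0:
        raise ValueError("universe too small for the given list and set sizes")

    table = np.array([[a, b], [c, d]])
    mle_or, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        sample_or = math.inf if a * d > 0 else 0.0
    else:
        sample_or = (a * d) / (b * c)
    odds_ratio = float(mle_or) if conditional_mle else sample_or

    if min(a, b, c, d) > 0 and math.isfinite(sample_or) and sample_or > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(sample_or) - _Z975 * se)
        ci_high = math.exp(math.log(sample_or) + _Z975 * se)
    else:
        ci_low, ci_high = math.nan, math.nan

    return EnrichmentResult(
        gene_set_name=gene_set_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=float(p),
    )


def specificity_scan(
    prioritized_genes,
    gene_sets,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test one prioritized list against many gene sets with Bonferroni
    correction over the number of sets.

    Gene symbols are compared case-insensitively after trimming. Set
    members outside the declared universe cannot be modelled and are
    dropped with a warning.
    """
    prioritized = {g.strip().upper() for g in prioritized_genes}
    m = len(gene_sets)
    if m == 0:
        raise ValueError("at least one gene set is required")
    results = []
    for gs in gene_sets:
        genes = gs.genes
        if len(genes) > universe_size - (len(prioritized) - len(prioritized & genes)):
            logger.warning(
                "gene set %s larger than the universe allows; clipping", gs.name
            )
        hits = len(prioritized & genes)
        res = fisher_overrepresentation(
            hits=hits,
            list_size=len(prioritized),
            set_size=len(genes),
            universe_size=universe_size,
            gene_set_name=gs.name,
        )
        res.p_corrected = min(1.0, m * res.p_two_sided)
        res.significant = res.p_corrected < alpha
        results.append(res)
    return results


def compare_log_or(result_1: EnrichmentResult, result_2: EnrichmentResult) -> OrComparison:
    """Compare two odds ratios on the log scale.

    Standard errors are recovered from the Wald 95% CIs as
    ``(log(ci_high) - log(ci_low)) / (2 * 1.96)``, so the comparison can be
    run from printed summary results as well as from fresh tables. The
    one-tailed p tests whether OR1 exceeds OR2.
    """
    for r in (result_1, result_2):
        if not (
            math.isfinite(r.odds_ratio)
            and math.isfinite(r.ci_low)
            and math.isfinite(r.ci_high)
            and r.ci_low > 0
        ):
            raise ValueError(f"non-finite OR/CI for {r.gene_set_name!r}")
    log1, log2 = math.log(result_1.odds_ratio), math.log(result_2.odds_ratio)
    se1 = (math.log(result_1.ci_high) - math.log(result_1.ci_low)) / (2 * _Z975)
    se2 = (math.log(result_2.ci_high) - math.log(result_2.ci_low)) / (2 * _Z975)
    z = (log1 - log2) / math.sqrt(se1**2 + se2**2)
    p = float(stats.norm.sf(z))
    return OrComparison(
        log_or_1=log1, log_or_2=log2, se_1=se1, se_2=se2, z=z, p_one_tailed=p
    )


def welch_t(group_1_values, group_2_values) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns (t, df, p_two_sided).
    """
    x = np.asarray(group_1_values, dtype=float)
    y = np.asarray(group_2_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)
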