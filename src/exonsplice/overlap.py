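"""Cross-study gene-set agreement: Dice similarity and overlap enrichment.

Two studies of the same biological system rarely use identical platforms or
pipelines, so their significant gene sets differ in size; the Dice
coefficient ``D = 2|A n B| / (|A| + |B|)`` is therefore reported alongside
its maximum attainable value for the given set sizes,
``D_max = 2 min(|A|,|B|) / (|A| + |B|)``, and the percent overlap
``D / D_max x 100``.  Enrichment of the intersection beyond chance is
assessed with a one-tailed Pearson chi-square test on the 2x2 membership
table over an explicitly supplied gene universe (no default universe is
assumed, since the choice materially changes the test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .models import ParameterError


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    intersection: int
    dice: float
    dice_max: float
    percent_overlap: float
    universe: int | None = None
    chi2_stat: float | None = None
    chi2_p_one_tailed: float | None = None


def dice_coefficient(set_a, set_b) -> float:
    """Dice similarity ``2|A n B| / (|A| + |B|)`` of two finite sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ParameterError("Dice coefficient undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def dice_max_and_percent(
    n_a: int, n_b: int, observed_dice: float
) -> tuple[float, float]:
    """Maximum attainable Dice for the set sizes, and observed/max x 100."""
    if n_a <= 0 or n_b <= 0:
        raise ParameterError("set sizes must be positive")
    dice_max = 2.0 * min(n_a, n_b) / (n_a + n_b)
    return dice_max, observed_dice / dice_max * 100.0


def overlap_chi_square(
    intersection: int, n_a: int, n_b: int, universe: int
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) with a directional tail.

    The 2x2 table crosses membership in A with membership in B over
    ``universe`` genes.  One-tailed p is half the two-sided chi-square(1)
    p-value when the observed intersection exceeds its expectation,
    ``1 - p/2`` otherwise, and 0.5 exactly at the expectation.
    """
    if universe < n_a + n_b - intersection:
        raise ParameterError("universe smaller than |A u B|")
    a = float(intersection)
    b = float(n_a - intersection)
    c = float(n_b - intersection)
    d = float(universe - n_a - n_b + intersection)
    if min(a, b, c, d) < 0:
        raise ParameterError("inconsistent counts")
    n = a + b + c + d
    expected = [
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    ]
    if min(expected) < 1.0:
        warnings.warn("overlap_chi_square: an expected cell is below 1")
    stat = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p_two = float(stats.chi2.sf(stat, df=1))
    exp_a = n_a * n_b / float(universe)
    if intersection > exp_a:
        p_one = p_two / 2.0
    elif intersection < exp_a:
        p_one = 1.0 - p_two / 2.0
    else:
        p_one = 0.5
    return float(stat), p_one


def compare_gene_sets(set_a, set_b, universe: int | None = None) -> OverlapResult:
    """Full agreement summary for two gene sets (chi-square needs a universe)."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    dice = dice_coefficient(a, b)
    dice_max, percent = dice_max_and_percent(len(a), len(b), dice)
    res = OverlapResult(
        n_a=len(a), n_b=len(b), intersection=inter,
        dice=dice, dice_max=dice_max, percent_overlap=percent,
    )
    if universe is not None:
        res.universe = int(universe)
        res.chi2_stat, res.chi2_p_one_tailed = overlap_chi_square(
            inter, len(a), len(b), int(universe)
        )
    return res
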