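"""The three minimum sample-size criteria for multinomial prediction models.

Criterion (i) targets the shrinkage factor of every sub-model of the
multinomial logistic regression.  Because the sub-models are parametrically
equivalent to distinct ("one-vs-one") binary logistic models, the binary
shrinkage-based sample-size formula

    m = Q / ((S - 1) * ln(1 - R²_adj / S))

is applied to every unordered pair of outcome categories {k, r} (k > r),
using the pair's anticipated Cox-Snell R².  The pair-subset size ``m_{k,r}``
is inflated to a whole-cohort size ``n_{k,r} = m_{k,r} / p_{k,r}`` and the
criterion's requirement is the maximum across pairs.

Criterion (ii) bounds the difference between apparent and optimism-adjusted
Nagelkerke R² of the overall multinomial model by delta, which translates
into a lower bound on the required shrinkage and hence on n.

Criterion (iii) requires each category proportion to be estimated within an
absolute margin of error delta, simultaneously across all K categories, via
the Goodman / Quesenberry-Hurst chi-squared construction (1 df, upper-tail
probability alpha/K).

The final minimum sample size is the maximum across the three criteria.
An events-per-variable comparator and the two mitigation operations for
infeasible sizes (category merging, per-pair shrinkage relaxation) round out
the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .outcome_model import (
    OutcomeDistribution,
    RsqEstimates,
    max_r2_pair,
)

__all__ = [
    "SizingConfig",
    "PairwiseEvidence",
    "CriterionResult",
    "SampleSizeReport",
    "UnattainableShrinkageError",
    "binary_shrinkage_size",
    "criterion_i",
    "criterion_i_heuristic_direct",
    "criterion_ii",
    "criterion_iii",
    "final_size",
    "epv_size",
    "merge_categories",
]

HEURISTIC_DIRECT_WARNING = (
    "the heuristic (overall) shrinkage approach would not necessarily result "
    "in the required level of shrinkage in each sub-model; it is provided as "
    "a diagnostic only and the pairwise criterion (i) should be used instead"
)


class UnattainableShrinkageError(ValueError):
    """Targeted shrinkage cannot be attained at any sample size (R² >= S)."""


@dataclass(frozen=True)
class SizingConfig:
    """Tunable parameters of the sample-size calculation.

    Parameters
    ----------
    Q
        Candidate predictor parameters per sub-model (counting spline /
        polynomial and interaction terms separately), before any selection.
    s_target
        Targeted shrinkage factor for criterion (i); 0.9 targets <= 10%
        overfitting.
    s_target_overrides
        Optional per-pair relaxation, e.g. ``{(5, 3): 0.8}``; keys are
        canonical (k, r) pairs with k > r.
    delta_r2
        Tolerated difference between apparent and adjusted Nagelkerke R²
        (criterion ii).
    delta_precision
        Absolute margin of error for every category proportion
        (criterion iii).
    alpha
        Significance level for the simultaneous intervals of criterion (iii).
    rounding
        ``"ceil"`` (default, conservative) or ``"nearest"``; applied to
        final per-pair / per-category sizes only, intermediates stay
        unrounded.
    pointwise
        If True, criterion (iii) uses pointwise normal intervals
        (``z_{1-alpha/2}²``) per category instead of the simultaneous
        chi-squared construction; for audit against binary-outcome
        conventions.
    """

    Q: int
    s_target: float = 0.9
    s_target_overrides: Mapping[tuple[int, int], float] = field(default_factory=dict)
    delta_r2: float = 0.05
    delta_precision: float = 0.05
    alpha: float = 0.05
    rounding: str = "ceil"
    pointwise: bool = False

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be a positive integer")
        for name, v in (
            ("s_target", self.s_target),
            ("delta_r2", self.delta_r2),
            ("delta_precision", self.delta_precision),
            ("alpha", self.alpha),
        ):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for pair, s in self.s_target_overrides.items():
            k, r = pair
            if k <= r:
                raise ValueError(f"override pair {pair} must be canonical (k > r)")
            if not 0.0 < s < 1.0:
                raise ValueError(f"override shrinkage for {pair} must lie in (0, 1)")
        if self.rounding not in ("ceil", "nearest"):
            raise ValueError("rounding must be 'ceil' or 'nearest'")

    def s_for_pair(self, pair: tuple[int, int]) -> float:
        return self.s_target_overrides.get(pair, self.s_target)

    def round_size(self, x: float) -> int:
        if self.rounding == "ceil":
            # guard against float dust pushing an exact integer up
            return math.ceil(x - 1e-9)
        return math.floor(x + 0.5)


@dataclass(frozen=True)
class PairwiseEvidence:
    """Anticipated Cox-Snell R² for every distinct logistic model {k, r}.

    ``r2`` maps canonical pairs (k, r), k > r, to optimism-adjusted
    Cox-Snell R² values; ``provenance`` records where each came from
    (reported / from_cstat_simulation / from_nagelkerke_assumption).
    ``overall`` optionally carries the overall multinomial R² estimates
    consumed by criterion (ii).
    """

    r2: Mapping[tuple[int, int], float]
    provenance: Mapping[tuple[int, int], str] = field(default_factory=dict)
    overall: Optional[RsqEstimates] = None

    def __post_init__(self) -> None:
        for pair, v in self.r2.items():
            k, r = pair
            if k <= r:
                raise ValueError(f"evidence pair {pair} must be canonical (k > r)")
            if not 0.0 < v < 1.0:
                raise ValueError(f"R² for pair {pair} must lie in (0, 1), got {v}")

    def validate_against(self, dist: OutcomeDistribution) -> None:
        """Check completeness and the per-pair upper bound max_r2_pair."""
        missing = [p for p in dist.pairs() if p not in self.r2]
        if missing:
            raise ValueError(
                "missing pairwise R² evidence for pairs: "
                + ", ".join(str(p) for p in missing)
            )
        for (k, r), v in self.r2.items():
            mx = max_r2_pair(dist.count(k), dist.count(r))
            if v >= mx:
                raise ValueError(
                    f"R² for pair ({k},{r}) is {v}, at or above its maximum "
                    f"attainable value {mx:.4f}"
                )


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of one criterion: its overall n and the element attaining it."""

    criterion: str  # "i" | "ii" | "iii"
    n: int
    per_pair_m: Optional[dict[tuple[int, int], float]] = None
    per_pair_n: Optional[dict[tuple[int, int], int]] = None
    per_category_n: Optional[dict[int, int]] = None
    binding: object = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class SampleSizeReport:
    """Aggregated result: the three criteria, the final maximum, and echoes."""

    criterion_i: CriterionResult
    criterion_ii: CriterionResult
    criterion_iii: CriterionResult
    final_n: int
    binding_criterion: str
    expected_counts: tuple[int, ...]
    inputs: dict
    warnings: tuple[str, ...] = ()
    epv_comparison: Optional[dict[float, int]] = None


def binary_shrinkage_size(Q: int, S: float, r2_adj: float) -> float:
    """Pair-subset size targeting shrinkage S for a binary logistic model.

    ``Q / ((S - 1) * ln(1 - r2_adj / S))``, returned unrounded.  Strictly
    increasing in Q and S, decreasing in r2_adj.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if not 0.0 < S < 1.0:
        raise ValueError("S must lie in (0, 1)")
    if not 0.0 < r2_adj < 1.0:
        raise ValueError("r2_adj must lie in (0, 1)")
    if r2_adj >= S:
        raise UnattainableShrinkageError(
            f"targeted shrinkage S={S} is unattainable for R²_adj={r2_adj} "
            "(requires R²_adj < S)"
        )
    return Q / ((S - 1.0) * math.log(1.0 - r2_adj / S))


def criterion_i(
    dist: OutcomeDistribution,
    evidence: PairwiseEvidence,
    cfg: SizingConfig,
) -> CriterionResult:
    """Pairwise shrinkage criterion across all distinct logistic models.

    For each canonical pair (k, r), k > r, computes the pair-subset size
    ``m_{k,r}`` from the binary shrinkage formula at the pair's (possibly
    overridden) shrinkage target, inflates by the pairwise cohort proportion
    to ``n_{k,r} = m_{k,r} / p_{k,r}``, and takes the maximum.
    """
    evidence.validate_against(dist)
    per_m: dict[tuple[int, int], float] = {}
    per_n: dict[tuple[int, int], int] = {}
    for pair in dist.pairs():
        k, r = pair
        s = cfg.s_for_pair(pair)
        try:
            m = binary_shrinkage_size(cfg.Q, s, evidence.r2[pair])
        except UnattainableShrinkageError as exc:
            raise UnattainableShrinkageError(
                f"pair ({k},{r}): {exc}"
            ) from exc
        per_m[pair] = m
        per_n[pair] = cfg.round_size(m / dist.p_pair(k, r))
    binding = max(per_n, key=lambda p: per_n[p])
    return CriterionResult(
        criterion="i",
        n=per_n[binding],
        per_pair_m=per_m,
        per_pair_n=per_n,
        binding=binding,
    )


def criterion_i_heuristic_direct(
    dist: OutcomeDistribution,
    overall: RsqEstimates,
    cfg: SizingConfig,
) -> int:
    """Rejected direct approach: size the overall heuristic shrinkage factor.

    Applies the binary formula with (K-1)*Q parameters and the overall
    multinomial Cox-Snell R².  Exposed for comparison only: targeting the
    overall heuristic shrinkage does not guarantee the required shrinkage in
    each sub-model, so some sub-models may still be overfit.  Always warns.
    """
    warnings.warn(HEURISTIC_DIRECT_WARNING, stacklevel=2)
    if overall.r2_cs_adj is None:
        raise ValueError("overall r2_cs_adj is required")
    total_q = (dist.K - 1) * cfg.Q
    n = binary_shrinkage_size(total_q, cfg.s_target, overall.r2_cs_adj)
    return cfg.round_size(n)


def criterion_ii(K: int, cfg: SizingConfig, overall: RsqEstimates) -> CriterionResult:
    """Bound the apparent-minus-adjusted Nagelkerke R² difference by delta.

    The difference is <= delta when the heuristic shrinkage satisfies
    ``S >= R² / (R² + delta * max_R²)``; substituting that bound into the
    (K-1)*Q-parameter shrinkage formula gives the smallest integer n with

        n >= (K-1)Q / [(R²/(R² + d·max) - 1) · ln(1 - R² - d·max)].
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if overall.r2_cs_adj is None or overall.max_r2_cs is None:
        raise ValueError("overall r2_cs_adj and max_r2_cs are required")
    r2 = overall.r2_cs_adj
    mx = overall.max_r2_cs
    d = cfg.delta_r2
    if r2 + d * mx >= 1.0:
        raise ValueError(
            f"R² + delta*max = {r2 + d * mx:.4f} >= 1; criterion (ii) is undefined"
        )
    if r2 <= 0.0:
        raise ValueError("overall r2_cs_adj must be positive")
    s_bound = r2 / (r2 + d * mx)
    n_raw = ((K - 1) * cfg.Q) / ((s_bound - 1.0) * math.log(1.0 - r2 - d * mx))
    return CriterionResult(criterion="ii", n=cfg.round_size(n_raw), binding=None)


def criterion_iii(dist: OutcomeDistribution, cfg: SizingConfig) -> CriterionResult:
    """Simultaneous precision of all K category proportions.

    ``n_k = chi²_{1, upper alpha/K} * p_k (1 - p_k) / delta²`` per category;
    the requirement is the maximum.  With ``pointwise=True`` the multiplier
    is ``z_{1-alpha/2}²`` instead (no simultaneity adjustment).
    """
    if cfg.pointwise:
        mult = stats.norm.ppf(1.0 - cfg.alpha / 2.0) ** 2
    else:
        mult = stats.chi2.ppf(1.0 - cfg.alpha / dist.K, df=1)
    warns: list[str] = []
    per_cat: dict[int, int] = {}
    for k in range(1, dist.K + 1):
        p = dist.p(k)
        if p in (0.0, 1.0):
            warns.append(
                f"category {k} has proportion {p:g}; it contributes no "
                "precision requirement"
            )
            per_cat[k] = 0
            continue
        per_cat[k] = cfg.round_size(mult * p * (1.0 - p) / cfg.delta_precision**2)
    binding = max(per_cat, key=lambda k: per_cat[k])
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return CriterionResult(
        criterion="iii",
        n=per_cat[binding],
        per_category_n=per_cat,
        binding=binding,
        warnings=tuple(warns),
    )


def final_size(
    crit_i: CriterionResult,
    crit_ii: CriterionResult,
    crit_iii: CriterionResult,
    dist: OutcomeDistribution,
    inputs: Optional[dict] = None,
    extra_warnings: Iterable[str] = (),
    epv_comparison: Optional[dict[float, int]] = None,
) -> SampleSizeReport:
    """Aggregate the three criteria into the final minimum sample size.

    The final n is the maximum of the three; expected per-category event
    counts at that n are reported, with the integer-rounding residual
    assigned to the largest category so the counts sum exactly to n.
    """
    results = {"i": crit_i, "ii": crit_ii, "iii": crit_iii}
    binding = max(results, key=lambda c: results[c].n)
    n = results[binding].n
    expected = [round(n * p) for p in dist.proportions]
    expected[expected.index(max(expected))] += n - sum(expected)
    all_warnings = tuple(extra_warnings) + crit_i.warnings + crit_ii.warnings + crit_iii.warnings
    return SampleSizeReport(
        criterion_i=crit_i,
        criterion_ii=crit_ii,
        criterion_iii=crit_iii,
        final_n=n,
        binding_criterion=binding,
        expected_counts=tuple(expected),
        inputs=dict(inputs or {}),
        warnings=all_warnings,
        epv_comparison=epv_comparison,
    )


def epv_size(epv: float, Q: int, dist: OutcomeDistribution) -> int:
    """Events-per-variable comparator: smallest n with min_k(n p_k) >= epv*Q.

    A legacy rule-of-thumb reported for contrast only; it is not one of the
    criteria and carries no shrinkage or precision guarantee.
    """
    if epv <= 0:
        raise ValueError("epv must be positive")
    p_min = min(dist.proportions)
    if p_min == 0.0:
        raise ValueError("EPV comparator undefined with an empty category")
    return math.ceil(epv * Q / p_min - 1e-9)


def merge_categories(
    dist: OutcomeDistribution,
    evidence: Optional[PairwiseEvidence],
    merge: Sequence[set[int] | frozenset[int] | Sequence[int]],
) -> tuple[OutcomeDistribution, Optional[PairwiseEvidence]]:
    """Merge outcome categories, the first mitigation for infeasible sizes.

    ``merge`` is a list of disjoint category-label sets; each set collapses
    into a single category placed at the position of its smallest original
    label, and categories are relabelled 1..K'.  Pairwise evidence for pairs
    touching any merged category is dropped (merging changes the distinct
    logistic models, so stale R² values must be re-supplied); evidence for
    untouched pairs carries over under the new labels.
    """
    sets = [frozenset(int(c) for c in s) for s in merge]
    seen: set[int] = set()
    for s in sets:
        if not s:
            raise ValueError("empty merge set")
        for c in s:
            if not 1 <= c <= dist.K:
                raise ValueError(f"category {c} does not exist (K={dist.K})")
            if c in seen:
                raise ValueError(f"category {c} appears in more than one merge set")
            seen.add(c)

    # group id = smallest original label in the group
    group_of: dict[int, int] = {}
    for s in sets:
        gid = min(s)
        for c in s:
            group_of[c] = gid
    for c in range(1, dist.K + 1):
        group_of.setdefault(c, c)
    gids = sorted(set(group_of.values()))
    if len(gids) < 2:
        raise ValueError("merging must leave at least 2 categories")
    new_label = {gid: i + 1 for i, gid in enumerate(gids)}

    new_counts = [0] * len(gids)
    for c in range(1, dist.K + 1):
        new_counts[new_label[group_of[c]] - 1] += dist.count(c)
    new_dist = OutcomeDistribution(tuple(new_counts))

    if evidence is None:
        return new_dist, None
    merged_cats = {c for s in sets if len(s) > 1 for c in s}
    new_r2: dict[tuple[int, int], float] = {}
    new_prov: dict[tuple[int, int], str] = {}
    for (k, r), v in evidence.r2.items():
        if k in merged_cats or r in merged_cats:
            continue  # stale under the new category structure
        nk, nr = new_label[group_of[k]], new_label[group_of[r]]
        pair = (max(nk, nr), min(nk, nr))
        new_r2[pair] = v
        if (k, r) in evidence.provenance:
            new_prov[pair] = evidence.provenance[(k, r)]
    return new_dist, PairwiseEvidence(r2=new_r2, provenance=new_prov, overall=None)
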