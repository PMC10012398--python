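"""Outcome-distribution arithmetic and likelihood-based R-squared utilities.

A clinical prediction model for a K-category nominal outcome is a multinomial
logistic regression with K-1 sub-models against a reference category.  The
sample-size criteria implemented in :mod:`mnlr_samplesize.sizing_criteria`
consume two families of quantities that depend only on the anticipated outcome
distribution:

* the maximum attainable Cox-Snell R-squared of the full multinomial model,
  ``1 - (prod_k p_k^{p_k})^2``, equivalently ``1 - exp(2*lnL_null/n)`` with
  ``lnL_null = sum_k E_k ln(E_k/n)`` the intercept-only log-likelihood;
* the analogous pairwise maxima for each distinct ("one-vs-one") logistic
  regression model restricted to a pair of outcome categories {k, r}, driven
  by the pairwise outcome fraction ``phi = E_k/(E_k + E_r)``.

Nagelkerke's R-squared rescales Cox-Snell by its maximum, so an assumed
Nagelkerke value converts to the Cox-Snell scale by a single product
(:func:`r2_from_nagelkerke`).

Categories are labelled 1..K throughout, matching the convention that
category 1 is the (default) reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

__all__ = [
    "OutcomeDistribution",
    "RsqEstimates",
    "EmptyCategoryError",
    "lnl_null",
    "lnl_null_pair",
    "max_r2_multinomial",
    "max_r2_pair",
    "r2_from_nagelkerke",
]


class EmptyCategoryError(ValueError):
    """Raised when a likelihood quantity is requested for an empty category."""


@dataclass(frozen=True)
class OutcomeDistribution:
    """Anticipated distribution of a K-category outcome in the target cohort.

    Parameters
    ----------
    counts
        Per-category event counts ``E_k`` (length K >= 2, non-negative).
    n
        Total cohort size.  Defaults to ``sum(counts)`` and must equal it.

    Notes
    -----
    Categories are labelled ``1..K``.  Pairwise quantities follow the
    convention ``p_pair(k, r) = p_pair(r, k)`` and
    ``phi_pair(r, k) = 1 - phi_pair(k, r)``.
    """

    counts: tuple[int, ...]
    n: int = 0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) < 2:
            raise ValueError("an outcome distribution needs at least 2 categories")
        if any(c < 0 for c in counts):
            raise ValueError("category counts must be non-negative")
        total = sum(counts)
        if total <= 0:
            raise ValueError("total count must be positive")
        object.__setattr__(self, "counts", counts)
        if self.n == 0:
            object.__setattr__(self, "n", total)
        elif self.n != total:
            raise ValueError(f"n={self.n} does not match sum(counts)={total}")

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "OutcomeDistribution":
        return cls(tuple(counts))

    @classmethod
    def from_proportions(cls, proportions: Sequence[float], n: int) -> "OutcomeDistribution":
        """Build from category proportions and a nominal cohort size.

        Proportions off unity by more than rounding slack (0.01) are an
        error; smaller discrepancies are renormalised.  The implied counts
        ``p_k * n`` are rounded to the nearest integer with a warning, since
        downstream likelihood formulas consume counts.
        """
        props = [float(p) for p in proportions]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        s = sum(props)
        if abs(s - 1.0) > 0.01:
            raise ValueError(f"proportions sum to {s:.4f}, not 1")
        if abs(s - 1.0) > 1e-12:
            props = [p / s for p in props]
        counts = [round(p * n) for p in props]
        warnings.warn(
            "proportions converted to counts by rounding p_k*n to the nearest "
            "integer; likelihood quantities use the rounded counts",
            stacklevel=2,
        )
        # preserve the nominal n: assign any rounding residual to the largest category
        counts[counts.index(max(counts))] += n - sum(counts)
        return cls(tuple(counts), n)

    @property
    def K(self) -> int:
        return len(self.counts)

    def _check_label(self, k: int) -> None:
        if not 1 <= k <= self.K:
            raise IndexError(f"category label {k} outside 1..{self.K}")

    def count(self, k: int) -> int:
        self._check_label(k)
        return self.counts[k - 1]

    def p(self, k: int) -> float:
        """Proportion of the cohort with outcome category k."""
        return self.count(k) / self.n

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.counts)

    def p_pair(self, k: int, r: int) -> float:
        """Proportion of the cohort with outcome in {k, r}."""
        if k == r:
            raise ValueError("pair requires two distinct categories")
        return (self.count(k) + self.count(r)) / self.n

    def phi_pair(self, k: int, r: int) -> float:
        """Pairwise outcome fraction E_k / (E_k + E_r) among the pair subset."""
        if k == r:
            raise ValueError("pair requires two distinct categories")
        ek, er = self.count(k), self.count(r)
        if ek + er == 0:
            raise EmptyCategoryError(f"pair ({k},{r}) has no events")
        return ek / (ek + er)

    def pairs(self) -> Iterator[tuple[int, int]]:
        """All unordered pairs, canonically ordered as (k, r) with k > r."""
        for r in range(1, self.K + 1):
            for k in range(r + 1, self.K + 1):
                yield (k, r)

    def _require_positive(self) -> None:
        for label, c in enumerate(self.counts, start=1):
            if c == 0:
                raise EmptyCategoryError(
                    f"category {label} has zero events; likelihood quantities "
                    "are undefined (drop or merge the category explicitly)"
                )


def lnl_null(dist: OutcomeDistribution) -> float:
    """Intercept-only multinomial log-likelihood, ``sum_k E_k ln(E_k/n)``."""
    dist._require_positive()
    return sum(e * math.log(e / dist.n) for e in dist.counts)


def lnl_null_pair(e_k: int, e_r: int) -> float:
    """Intercept-only log-likelihood of the distinct logistic model for {k, r}.

    ``E_k ln(E_k/(E_k+E_r)) + E_r ln(E_r/(E_k+E_r))``.
    """
    if e_k < 1 or e_r < 1:
        raise EmptyCategoryError("both pair counts must be >= 1")
    m = e_k + e_r
    return e_k * math.log(e_k / m) + e_r * math.log(e_r / m)


def max_r2_multinomial(dist: OutcomeDistribution) -> float:
    """Maximum attainable Cox-Snell R-squared of the multinomial model.

    ``1 - (prod_k p_k^{p_k})^2``; agrees with ``1 - exp(2*lnL_null/n)``.
    """
    dist._require_positive()
    log_prod = sum(p * math.log(p) for p in dist.proportions)
    return 1.0 - math.exp(2.0 * log_prod)


def max_r2_pair(e_k: int, e_r: int) -> float:
    """Maximum attainable Cox-Snell R-squared of the {k, r} distinct model.

    ``1 - (phi^phi (1-phi)^(1-phi))^2`` with ``phi = E_k/(E_k+E_r)``;
    symmetric in its arguments.
    """
    if e_k < 1 or e_r < 1:
        raise EmptyCategoryError("both pair counts must be >= 1")
    phi = e_k / (e_k + e_r)
    return 1.0 - math.exp(2.0 * (phi * math.log(phi) + (1.0 - phi) * math.log1p(-phi)))


def r2_from_nagelkerke(r2_nagelkerke: float, max_r2: float) -> float:
    """Cox-Snell R-squared implied by a Nagelkerke R-squared and a maximum.

    Nagelkerke's statistic is Cox-Snell rescaled by its maximum attainable
    value, so the conversion is the plain product.  The conventional
    conservative assumption when no prior model is available is an
    optimism-adjusted Nagelkerke R-squared of 0.15.
    """
    if not 0.0 <= r2_nagelkerke <= 1.0:
        raise ValueError("Nagelkerke R^2 must lie in [0, 1]")
    if not 0.0 <= max_r2 < 1.0:
        raise ValueError("max Cox-Snell R^2 must lie in [0, 1)")
    return r2_nagelkerke * max_r2


Provenance = Literal["reported", "from_nagelkerke_assumption", "from_cstat_simulation"]


@dataclass(frozen=True)
class RsqEstimates:
    """Bundle of Cox-Snell / Nagelkerke R-squared quantities for one model.

    Any subset may be present; invariants are checked on whichever fields are.
    """

    r2_cs_app: Optional[float] = None
    r2_cs_adj: Optional[float] = None
    max_r2_cs: Optional[float] = None
    r2_nagelkerke: Optional[float] = None
    lnl_null: Optional[float] = None
    provenance: Provenance = "reported"

    def __post_init__(self) -> None:
        if self.max_r2_cs is not None and not 0.0 <= self.max_r2_cs < 1.0:
            raise ValueError("max_r2_cs must lie in [0, 1)")
        for name in ("r2_cs_app", "r2_cs_adj"):
            v = getattr(self, name)
            if v is None:
                continue
            if v < 0.0:
                raise ValueError(f"{name} must be non-negative")
            if self.max_r2_cs is not None and v > self.max_r2_cs + 1e-12:
                raise ValueError(f"{name}={v} exceeds max_r2_cs={self.max_r2_cs}")
        if (
            self.r2_nagelkerke is not None
            and self.r2_cs_adj is not None
            and self.max_r2_cs is not None
        ):
            implied = self.r2_cs_adj / self.max_r2_cs
            if abs(implied - self.r2_nagelkerke) > 1e-12:
                raise ValueError(
                    "inconsistent Nagelkerke R^2: "
                    f"{self.r2_nagelkerke} vs r2_cs_adj/max = {implied}"
                )
        if self.lnl_null is not None and self.lnl_null > 0.0:
            raise ValueError("lnl_null must be <= 0")

    @classmethod
    def from_nagelkerke(
        cls, r2_nagelkerke: float, dist: OutcomeDistribution
    ) -> "RsqEstimates":
        """Overall-model estimates under an assumed Nagelkerke R-squared."""
        mx = max_r2_multinomial(dist)
        return cls(
            r2_cs_adj=r2_from_nagelkerke(r2_nagelkerke, mx),
            max_r2_cs=mx,
            r2_nagelkerke=r2_nagelkerke,
            lnl_null=lnl_null(dist),
            provenance="from_nagelkerke_assumption",
        )
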