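"""Simulation harness verifying the pairwise shrinkage criterion.

The pairwise criterion (criterion i in :mod:`mnlr_samplesize.sizing_criteria`)
claims that developing a multinomial logistic regression on the sample size
it returns targets every sub-model-specific shrinkage factor at or above the
chosen threshold.  This module checks that claim empirically:

1. a multinomial data-generating process is specified (coefficients per
   sub-model, intercepts calibrated to hit target category proportions,
   independent standard-normal covariates);
2. the "true" pairwise Cox-Snell R² values are estimated once from a large
   pilot sample and fed to the sizing criterion;
3. many development datasets of the computed size are simulated; on each, the
   model is fitted and three families of shrinkage estimates are computed on
   independent validation data:

   * ``S_MN,k,r`` — sub-model shrinkage under the multinomial recalibration
     framework (a 2(K-1)-parameter model giving each equation its own
     intercept and a slope on its own linear predictor);
   * ``S_DL,k,r`` — the calibration slope of the distinct ("one-vs-one")
     logistic model on the pair subset;
   * ``S_VH_MN`` — the overall heuristic shrinkage ``1 - (K-1)Q/LR``.

The headline check is that the median ``S_MN,k,r`` sits at the targeted
shrinkage for every pair, and that ``S_DL`` and ``S_MN`` agree closely at
the criterion's sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .outcome_model import OutcomeDistribution, lnl_null
from .sizing_criteria import PairwiseEvidence, SizingConfig, criterion_i

__all__ = [
    "SimulationDesign",
    "MultinomialFit",
    "ShrinkageEstimates",
    "ExperimentSummary",
    "FlaggedReplicate",
    "default_design",
    "calibrated",
    "calibrate_intercepts",
    "pilot_pairwise_r2",
    "simulate_dataset",
    "fit_multinomial",
    "heuristic_shrinkage",
    "submodel_shrinkage_vanhoorde",
    "distinct_logistic_shrinkage",
    "run_experiment",
]


class FlaggedReplicate(RuntimeError):
    """A replicate excluded from summaries (separation / non-convergence)."""


@dataclass(frozen=True)
class SimulationDesign:
    """Data-generating process for the shrinkage experiment.

    ``beta`` has shape (Q, K-1): column k-2 holds the slope vector of the
    sub-model for category k against reference category 1.  Covariates are
    independent standard normal.  ``intercepts`` (length K-1) are usually
    left unset and calibrated to hit ``target_proportions``.
    """

    K: int
    Q: int
    beta: np.ndarray
    target_proportions: tuple[float, ...]
    intercepts: Optional[np.ndarray] = None
    n_dev: Optional[int] = None
    n_val_factor: int = 100
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (self.Q, self.K - 1):
            raise ValueError(
                f"beta must have shape (Q, K-1) = ({self.Q}, {self.K - 1}), "
                f"got {beta.shape}"
            )
        object.__setattr__(self, "beta", beta)
        props = tuple(float(p) for p in self.target_proportions)
        if len(props) != self.K:
            raise ValueError("target_proportions must have length K")
        if abs(sum(props) - 1.0) > 1e-9 or any(p <= 0 for p in props):
            raise ValueError("target_proportions must be positive and sum to 1")
        object.__setattr__(self, "target_proportions", props)
        if self.intercepts is not None:
            ic = np.asarray(self.intercepts, dtype=float)
            if ic.shape != (self.K - 1,):
                raise ValueError("intercepts must have length K-1")
            object.__setattr__(self, "intercepts", ic)


def default_design(
    K: int = 3,
    Q: int = 5,
    effect_scale: float = 1.0,
    target_proportions: Optional[Sequence[float]] = None,
    n_sims: int = 200,
    seed: int = 0,
) -> SimulationDesign:
    """Opinionated default design with symmetric, moderate covariate effects.

    Categories sit at the vertices of a regular simplex in coefficient
    space (``beta_k = effect_scale * (e_k - e_1)`` in the first K covariate
    dimensions), so every pair has the same coefficient separation
    ``effect_scale * sqrt(2)``.  At the default scale of 1 this yields
    pairwise C-statistics in the middle of the 0.7-0.85 range typical of
    clinical prediction models.  Requires Q >= K.
    """
    if Q < K:
        raise ValueError("the simplex construction needs Q >= K")
    if target_proportions is None:
        target_proportions = tuple(1.0 / K for _ in range(K))
    beta = np.zeros((Q, K - 1))
    for j in range(K - 1):  # category k = j + 2
        beta[j + 1, j] = effect_scale
        beta[0, j] = -effect_scale
    return SimulationDesign(
        K=K,
        Q=Q,
        beta=beta,
        target_proportions=tuple(target_proportions),
        n_sims=n_sims,
        seed=seed,
    )


def _probabilities(
    X: np.ndarray, intercepts: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Category probabilities (n, K) under the softmax model, category 1 ref."""
    eta = intercepts + X @ beta  # (n, K-1)
    full = np.column_stack([np.zeros(len(X)), eta])
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def calibrate_intercepts(
    design: SimulationDesign,
    calibration_size: int = 1_000_000,
    tol: float = 0.002,
    max_iter: int = 200,
) -> np.ndarray:
    """Root-find intercepts so marginal proportions match the targets.

    With all slopes zero the closed form ``ln(p_k/p_1)`` is returned.
    Otherwise a fixed-point iteration on a fixed calibration sample of
    covariates adjusts each intercept by the log-ratio of target to current
    marginal probability (relative to the reference category) until the
    simulated marginals are within ``tol`` of the targets.  Deterministic
    given the design seed.
    """
    t = np.asarray(design.target_proportions)
    if not design.beta.any():
        return np.log(t[1:] / t[0])
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xCA11]))
    X = rng.standard_normal((calibration_size, design.Q))
    b0 = np.log(t[1:] / t[0])
    for _ in range(max_iter):
        pi = _probabilities(X, b0, design.beta).mean(axis=0)
        if np.abs(pi - t).max() < tol / 2.0:
            return b0
        b0 = b0 + np.log(t[1:] / pi[1:]) - math.log(t[0] / pi[0])
    raise RuntimeError(
        f"intercept calibration did not converge within {max_iter} iterations"
    )


def calibrated(design: SimulationDesign, calibration_size: int = 1_000_000) -> SimulationDesign:
    """Return a copy of the design with calibrated intercepts filled in."""
    if design.intercepts is not None:
        return design
    return replace(design, intercepts=calibrate_intercepts(design, calibration_size))


def simulate_dataset(
    design: SimulationDesign, replicate_seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one dataset: covariates X (n, Q) and labels y in 1..K.

    ``replicate_seed`` may be an int or a ``numpy.random.SeedSequence``;
    the sample size is ``design.n_dev``.
    """
    if design.intercepts is None:
        raise ValueError("design intercepts not calibrated")
    if design.n_dev is None:
        raise ValueError("design n_dev not set")
    return _draw(design, design.n_dev, replicate_seed)


def _draw(design: SimulationDesign, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, design.Q))
    probs = _probabilities(X, design.intercepts, design.beta)
    u = rng.random(n)
    y = 1 + (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    # guard against u falling exactly on 1.0 cumulative dust
    np.clip(y, 1, design.K, out=y)
    return X, y


@dataclass(frozen=True)
class MultinomialFit:
    """Maximum-likelihood multinomial fit, reference category 1."""

    K: int
    Q: int
    intercepts: np.ndarray  # (K-1,)
    coefs: np.ndarray  # (Q, K-1)
    lnl_model: float
    lnl_null: float
    lr: float
    converged: bool

    def coef_matrix(self) -> np.ndarray:
        """Slope coefficients as (Q, K) with a zero column for category 1."""
        return np.column_stack([np.zeros(self.Q), self.coefs])

    def pair_lp(self, X: np.ndarray, k: int, r: int) -> np.ndarray:
        """Linear predictor (slopes only) of sub-model k vs reference r."""
        B = self.coef_matrix()
        return X @ (B[:, k - 1] - B[:, r - 1])


_SEPARATION_COEF_BOUND = 20.0


def fit_multinomial(X: np.ndarray, y: np.ndarray) -> MultinomialFit:
    """Fit a multinomial logistic regression by maximum likelihood.

    Uses the statsmodels ``MNLogit`` Newton solver with category 1 as the
    reference.  The null log-likelihood is the closed-form intercept-only
    value from the observed counts, and ``lr = -2(lnL_null - lnL_model)``.

    Raises
    ------
    FlaggedReplicate
        If not all categories are present, the optimiser fails to converge,
        or coefficients diverge (complete separation).
    """
    import statsmodels.api as sm

    y = np.asarray(y)
    labels = np.unique(y)
    K = int(labels.max())
    if len(labels) != K or labels.min() != 1:
        raise FlaggedReplicate(
            f"not all categories 1..{K} present in the data (saw {labels.tolist()})"
        )
    X = np.asarray(X, dtype=float)
    n, Q = X.shape
    exog = np.column_stack([np.ones(n), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y - 1, exog).fit(method="newton", disp=0, maxiter=200)
        except Exception as exc:
            raise FlaggedReplicate(f"multinomial fit failed: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params)  # (Q+1, K-1)
    if not converged or np.abs(params).max() > _SEPARATION_COEF_BOUND:
        raise FlaggedReplicate(
            "multinomial fit did not converge or coefficients diverged "
            "(possible complete separation)"
        )
    counts = np.bincount(y, minlength=K + 1)[1:]
    lln = lnl_null(OutcomeDistribution(tuple(int(c) for c in counts)))
    llf = float(res.llf)
    return MultinomialFit(
        K=K,
        Q=Q,
        intercepts=params[0, :].copy(),
        coefs=params[1:, :].copy(),
        lnl_model=llf,
        lnl_null=lln,
        lr=max(0.0, 2.0 * (llf - lln)),
        converged=converged,
    )


def heuristic_shrinkage(lr: float, K: int, Q: int) -> float:
    """Overall heuristic shrinkage ``1 - (K-1)Q / LR`` of a multinomial fit.

    May be negative for very small LR; a warning is emitted in that case
    and the value returned as-is.
    """
    if lr <= 0.0:
        raise ValueError("heuristic shrinkage undefined for LR <= 0")
    s = 1.0 - (K - 1) * Q / lr
    if s < 0.0:
        warnings.warn(
            f"heuristic shrinkage is negative ({s:.3f}); the model explains "
            "less than its parameter count",
            stacklevel=2,
        )
    return s


def _logistic_fit(lp: np.ndarray, y01: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Two-parameter logistic fit (intercept + slope on lp); returns beta."""
    n = y01.size
    X = np.column_stack([np.ones(n), lp])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y01 - p)
        w = np.maximum(p * (1.0 - p), 1e-12)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FlaggedReplicate("singular Hessian in calibration-slope fit") from exc
        beta += step
        if np.abs(step).max() < 1e-10:
            return beta
    raise FlaggedReplicate("calibration-slope fit did not converge")


def _general_logistic_lr(X: np.ndarray, y01: np.ndarray, max_iter: int = 100) -> float:
    """LR statistic of a logistic fit with an intercept and all columns of X."""
    n = y01.size
    Xc = np.column_stack([np.ones(n), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(max_iter):
        eta = Xc @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xc.T @ (y01 - p)
        w = np.maximum(p * (1.0 - p), 1e-12)
        hess = (Xc * w[:, None]).T @ Xc
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < 1e-10:
            break
    else:
        raise FlaggedReplicate("pilot logistic fit did not converge")
    eta = Xc @ beta
    llf = float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))
    e1 = y01.sum()
    pbar = e1 / n
    lln = e1 * math.log(pbar) + (n - e1) * math.log1p(-pbar)
    return 2.0 * (llf - lln)


def submodel_shrinkage_vanhoorde(
    dev_fit: MultinomialFit,
    X_val: np.ndarray,
    y_val: np.ndarray,
    reference: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict[int, float]:
    """Sub-model shrinkage factors under the multinomial recalibration model.

    With reference category r, the development model's slope-only linear
    predictors ``LP_k`` are computed on the validation data and the
    2(K-1)-parameter recalibration model

        ln[P(Y=k)/P(Y=r)] = a_k + S_k * LP_k   (k != r)

    is fitted by maximum likelihood (Newton on the concave log-likelihood,
    each equation carrying a slope only on its own linear predictor).
    Returns ``{k: S_k}`` for all k != r.
    """
    K = dev_fit.K
    if not 1 <= reference <= K:
        raise ValueError(f"reference {reference} outside 1..{K}")
    others = [k for k in range(1, K + 1) if k != reference]
    m = len(others)
    n = len(y_val)
    LP = np.column_stack([dev_fit.pair_lp(X_val, k, reference) for k in others])
    Y = np.column_stack([(y_val == k).astype(float) for k in others])
    counts = np.array([max(Y[:, j].sum(), 1.0) for j in range(m)])
    n_ref = max(n - counts.sum(), 1.0)

    # theta layout: [a_1..a_m, s_1..s_m]
    theta = np.concatenate([np.log(counts / n_ref), np.ones(m)])
    for _ in range(max_iter):
        eta = theta[:m] + LP * theta[m:]
        full = np.column_stack([np.zeros(n), eta])
        full -= full.max(axis=1, keepdims=True)
        ex = np.exp(full)
        P = ex / ex.sum(axis=1, keepdims=True)  # col 0 = reference
        Pk = P[:, 1:]
        resid = Y - Pk
        grad = np.concatenate([resid.sum(axis=0), (resid * LP).sum(axis=0)])
        # Hessian blocks over equation pairs (j, l), design z_ij = (1, LP_ij)
        H = np.zeros((2 * m, 2 * m))
        for j in range(m):
            for l in range(j, m):
                wjl = Pk[:, j] * ((1.0 if j == l else 0.0) - Pk[:, l])
                h_aa = wjl.sum()
                h_as = (wjl * LP[:, l]).sum()
                h_sa = (wjl * LP[:, j]).sum()
                h_ss = (wjl * LP[:, j] * LP[:, l]).sum()
                H[j, l] += h_aa
                H[j, m + l] += h_as
                H[m + j, l] += h_sa
                H[m + j, m + l] += h_ss
                if l != j:
                    H[l, j] += h_aa
                    H[m + l, j] += h_as
                    H[l, m + j] += h_sa
                    H[m + l, m + j] += h_ss
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FlaggedReplicate("singular Hessian in recalibration fit") from exc
        theta += step
        if np.abs(step).max() < tol:
            return {k: float(theta[m + j]) for j, k in enumerate(others)}
    raise FlaggedReplicate("recalibration fit did not converge")


def distinct_logistic_shrinkage(
    dev_fit: MultinomialFit,
    X_val: np.ndarray,
    y_val: np.ndarray,
    pair: tuple[int, int],
) -> float:
    """Calibration slope of the pair's linear predictor on the pair subset.

    Fits ``logit P(Y=k | Y in {k,r}) = a + S * LP_{k,r}`` on the validation
    individuals with outcome in {k, r} and returns the slope S.
    """
    k, r = pair
    mask = (y_val == k) | (y_val == r)
    yb = (y_val[mask] == k).astype(float)
    if yb.sum() == 0 or yb.sum() == yb.size:
        raise FlaggedReplicate(f"validation subset for pair ({k},{r}) is one-sided")
    lp = dev_fit.pair_lp(X_val[mask], k, r)
    beta = _logistic_fit(lp, yb)
    return float(beta[1])


@dataclass(frozen=True)
class ShrinkageEstimates:
    """Per-replicate shrinkage estimates; summaries derive from these only."""

    pairs: tuple[tuple[int, int], ...]
    s_mn: dict[tuple[int, int], np.ndarray]
    s_dl: dict[tuple[int, int], np.ndarray]
    s_vh: np.ndarray
    n_excluded: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            mn, dl = self.s_mn[pair], self.s_dl[pair]
            rows.append(
                {
                    "pair": f"{pair[0]},{pair[1]}",
                    "median_s_mn": np.median(mn),
                    "mean_s_mn": mn.mean(),
                    "q2.5_s_mn": np.percentile(mn, 2.5),
                    "q97.5_s_mn": np.percentile(mn, 97.5),
                    "median_s_dl": np.median(dl),
                    "median_abs_diff": np.median(np.abs(dl - mn)),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentSummary:
    design: SimulationDesign
    n_dev: int
    n_val: int
    pilot_r2: dict[tuple[int, int], float]
    estimates: ShrinkageEstimates
    s_target: float
    headline_tolerance: float

    @property
    def meets_target(self) -> dict[tuple[int, int], bool]:
        """Headline check: median S_MN within tolerance of the target."""
        return {
            pair: bool(
                np.median(self.estimates.s_mn[pair])
                >= self.s_target - self.headline_tolerance
            )
            for pair in self.estimates.pairs
        }

    def to_dict(self) -> dict:
        est = self.estimates
        return {
            "n_dev": self.n_dev,
            "n_val": self.n_val,
            "n_sims_done": int(est.s_vh.size),
            "n_excluded": est.n_excluded,
            "s_target": self.s_target,
            "pilot_r2": {f"{k},{r}": v for (k, r), v in self.pilot_r2.items()},
            "s_vh_median": float(np.median(est.s_vh)) if est.s_vh.size else None,
            "pairs": {
                f"{k},{r}": {
                    "median_s_mn": float(np.median(est.s_mn[(k, r)])),
                    "median_s_dl": float(np.median(est.s_dl[(k, r)])),
                    "median_abs_diff": float(
                        np.median(np.abs(est.s_dl[(k, r)] - est.s_mn[(k, r)]))
                    ),
                    "meets_target": self.meets_target[(k, r)],
                }
                for (k, r) in est.pairs
            },
        }


def pilot_pairwise_r2(
    design: SimulationDesign, pilot_size: int = 1_000_000
) -> tuple[OutcomeDistribution, dict[tuple[int, int], float]]:
    """Estimate the DGP's pairwise Cox-Snell R² from one large pilot sample.

    For each pair {k, r} (k > r) a logistic model with all Q covariates is
    fitted on the pair subset and ``R² = 1 - exp(-LR/m_pair)`` recorded.  The
    observed pilot counts double as the outcome distribution for sizing.
    """
    design = calibrated(design, calibration_size=min(pilot_size, 1_000_000))
    X, y = _draw(design, pilot_size, np.random.SeedSequence([design.seed, 0x9101]))
    counts = np.bincount(y, minlength=design.K + 1)[1:]
    dist = OutcomeDistribution(tuple(int(c) for c in counts))
    r2: dict[tuple[int, int], float] = {}
    for pair in dist.pairs():
        k, r = pair
        mask = (y == k) | (y == r)
        yb = (y[mask] == k).astype(float)
        lr = _general_logistic_lr(X[mask], yb)
        r2[pair] = 1.0 - math.exp(-lr / mask.sum())
    return dist, r2


def run_experiment(
    design: SimulationDesign,
    cfg: SizingConfig,
    pilot_size: int = 1_000_000,
    headline_tolerance: float = 0.05,
) -> ExperimentSummary:
    """Size with criterion (i), then simulate to verify sub-model shrinkage.

    The pilot-estimated pairwise R² values feed the pairwise shrinkage
    criterion; development datasets of the resulting size are simulated
    ``design.n_sims`` times, each fitted and validated on an independent
    validation sample ``n_val_factor`` times larger.  Replicates flagged for
    separation or non-convergence are excluded and counted, never retried.
    """
    design = calibrated(design)
    dist, r2 = pilot_pairwise_r2(design, pilot_size)
    weak = [p for p, v in r2.items() if v < 1e-3]
    if weak:
        raise ValueError(
            f"pilot pairwise R² is ~0 for pairs {weak}: the design has no "
            "predictive signal there and shrinkage-based sizing is not "
            "meaningful"
        )
    evidence = PairwiseEvidence(
        r2=r2, provenance={p: "pilot_simulation" for p in r2}
    )
    if design.n_dev is None:
        n_dev = criterion_i(dist, evidence, cfg).n
        design = replace(design, n_dev=n_dev)
    n_dev = design.n_dev
    n_val = design.n_val_factor * n_dev

    pairs = tuple(dist.pairs())
    s_mn: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    s_dl: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    s_vh: list[float] = []
    n_excluded = 0

    master = np.random.SeedSequence([design.seed, 0xD3])
    rep_seeds = master.spawn(design.n_sims)
    references = sorted({r for (_, r) in pairs})
    for rep, rs in enumerate(rep_seeds):
        dev_seed, val_seed = rs.spawn(2)
        try:
            X_dev, y_dev = _draw(design, n_dev, dev_seed)
            fit = fit_multinomial(X_dev, y_dev)
            X_val, y_val = _draw(design, n_val, val_seed)
            rep_mn: dict[tuple[int, int], float] = {}
            for r in references:
                slopes = submodel_shrinkage_vanhoorde(fit, X_val, y_val, reference=r)
                for k, s in slopes.items():
                    if (k, r) in s_mn:
                        rep_mn[(k, r)] = s
            rep_dl = {
                pair: distinct_logistic_shrinkage(fit, X_val, y_val, pair)
                for pair in pairs
            }
        except FlaggedReplicate:
            n_excluded += 1
            continue
        for pair in pairs:
            s_mn[pair].append(rep_mn[pair])
            s_dl[pair].append(rep_dl[pair])
        s_vh.append(heuristic_shrinkage(fit.lr, design.K, design.Q))

    estimates = ShrinkageEstimates(
        pairs=pairs,
        s_mn={p: np.asarray(v) for p, v in s_mn.items()},
        s_dl={p: np.asarray(v) for p, v in s_dl.items()},
        s_vh=np.asarray(s_vh),
        n_excluded=n_excluded,
    )
    return ExperimentSummary(
        design=design,
        n_dev=n_dev,
        n_val=n_val,
        pilot_r2=r2,
        estimates=estimates,
        s_target=cfg.s_target,
        headline_tolerance=headline_tolerance,
    )
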