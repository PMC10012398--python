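"""Configuration, evidence resolution, and report rendering.

Ties the pieces together into the six-step workflow: choose Q; choose the
outcome distribution and R² inputs; compute criteria (i)-(iii); take the
maximum.  Pairwise R² evidence is resolved per pair with an explicit
precedence — a directly supplied Cox-Snell R² beats a C-statistic (converted
by simulation), which beats the conservative Nagelkerke-0.15 fallback — and
every resolution is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import yaml

from .cstat_to_r2 import CstatConversionSpec, r2_from_cstat
from .outcome_model import (
    OutcomeDistribution,
    RsqEstimates,
    max_r2_multinomial,
    max_r2_pair,
    r2_from_nagelkerke,
)
from .sizing_criteria import (
    CriterionResult,
    PairwiseEvidence,
    SampleSizeReport,
    SizingConfig,
    criterion_i,
    criterion_ii,
    criterion_iii,
    epv_size,
    final_size,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "run_sizing",
    "render_report",
    "report_to_dict",
    "report_from_dict",
]

logger = logging.getLogger("mnlr_samplesize")

DEFAULT_NAGELKERKE_FALLBACK = 0.15


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


def _require_keys(block: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


def _parse_pair_key(key: str, context: str) -> tuple[int, int]:
    try:
        k, r = (int(x) for x in str(key).split(","))
    except ValueError as exc:
        raise ConfigError(f"{context}: pair key {key!r} is not 'k,r'") from exc
    if k <= r:
        raise ConfigError(f"{context}: pair key {key!r} must have k > r")
    return (k, r)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for one sizing calculation."""

    dist: OutcomeDistribution
    sizing: SizingConfig
    pairwise_r2: dict[tuple[int, int], float] = field(default_factory=dict)
    pairwise_cstat: dict[tuple[int, int], float] = field(default_factory=dict)
    nagelkerke_fallback: float = DEFAULT_NAGELKERKE_FALLBACK
    overall_r2_cs_adj: Optional[float] = None
    sim_size: int = 1_000_000
    n_replicates: int = 10
    seed: int = 0
    epv: tuple[float, ...] = ()
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(data, Mapping):
            raise ConfigError("config must be a mapping")
        _require_keys(
            data,
            {"outcome", "predictors", "criteria", "evidence", "seed", "epv"},
            "config",
        )
        try:
            outcome = data["outcome"]
            predictors = data["predictors"]
        except KeyError as exc:
            raise ConfigError(f"missing required block: {exc}") from exc

        _require_keys(outcome, {"counts", "proportions", "n"}, "outcome")
        if "counts" in outcome:
            if "proportions" in outcome:
                raise ConfigError("outcome: give counts or proportions, not both")
            dist = OutcomeDistribution.from_counts(outcome["counts"])
        elif "proportions" in outcome:
            if "n" not in outcome:
                raise ConfigError("outcome: proportions require a total n")
            dist = OutcomeDistribution.from_proportions(
                outcome["proportions"], int(outcome["n"])
            )
        else:
            raise ConfigError("outcome: counts or proportions required")

        _require_keys(predictors, {"Q"}, "predictors")
        criteria = dict(data.get("criteria", {}))
        _require_keys(
            criteria,
            {
                "S_target",
                "S_target_overrides",
                "delta_r2",
                "delta_precision",
                "alpha",
                "rounding",
                "pointwise",
            },
            "criteria",
        )
        overrides = {
            _parse_pair_key(k, "S_target_overrides"): float(v)
            for k, v in dict(criteria.get("S_target_overrides", {})).items()
        }
        try:
            sizing = SizingConfig(
                Q=int(predictors["Q"]),
                s_target=float(criteria.get("S_target", 0.9)),
                s_target_overrides=overrides,
                delta_r2=float(criteria.get("delta_r2", 0.05)),
                delta_precision=float(criteria.get("delta_precision", 0.05)),
                alpha=float(criteria.get("alpha", 0.05)),
                rounding=str(criteria.get("rounding", "ceil")),
                pointwise=bool(criteria.get("pointwise", False)),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

        evidence = dict(data.get("evidence", {}))
        _require_keys(
            evidence,
            {
                "pairwise_r2",
                "pairwise_cstat",
                "nagelkerke_fallback",
                "overall_r2_cs_adj",
                "sim_size",
                "n_replicates",
            },
            "evidence",
        )
        pairwise_r2 = {
            _parse_pair_key(k, "pairwise_r2"): float(v)
            for k, v in dict(evidence.get("pairwise_r2", {})).items()
        }
        pairwise_cstat = {
            _parse_pair_key(k, "pairwise_cstat"): float(v)
            for k, v in dict(evidence.get("pairwise_cstat", {})).items()
        }
        epv = tuple(float(e) for e in data.get("epv", []))
        return cls(
            dist=dist,
            sizing=sizing,
            pairwise_r2=pairwise_r2,
            pairwise_cstat=pairwise_cstat,
            nagelkerke_fallback=float(
                evidence.get("nagelkerke_fallback", DEFAULT_NAGELKERKE_FALLBACK)
            ),
            overall_r2_cs_adj=(
                float(evidence["overall_r2_cs_adj"])
                if evidence.get("overall_r2_cs_adj") is not None
                else None
            ),
            sim_size=int(evidence.get("sim_size", 1_000_000)),
            n_replicates=int(evidence.get("n_replicates", 10)),
            seed=int(data.get("seed", 0)),
            epv=epv,
            raw=dict(data),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)


def resolve_evidence(config: RunConfig) -> PairwiseEvidence:
    """Resolve per-pair R² with precedence R² > C-statistic > fallback."""
    import numpy as np

    dist = config.dist
    r2: dict[tuple[int, int], float] = {}
    prov: dict[tuple[int, int], str] = {}
    for pair in dist.pairs():
        k, r = pair
        if pair in config.pairwise_r2:
            r2[pair] = config.pairwise_r2[pair]
            prov[pair] = "reported"
        elif pair in config.pairwise_cstat:
            pair_seed = int(
                np.random.SeedSequence([config.seed, k, r]).generate_state(1)[0]
                % (2**31)
            )
            res = r2_from_cstat(
                CstatConversionSpec(
                    c_statistic=config.pairwise_cstat[pair],
                    phi=dist.phi_pair(k, r),
                    sim_size=config.sim_size,
                    n_replicates=config.n_replicates,
                    seed=pair_seed,
                )
            )
            r2[pair] = res.r2
            prov[pair] = "from_cstat_simulation"
        else:
            r2[pair] = r2_from_nagelkerke(
                config.nagelkerke_fallback, max_r2_pair(dist.count(k), dist.count(r))
            )
            prov[pair] = "from_nagelkerke_assumption"
        logger.info(
            "pair (%d,%d): R2_CS = %.4f [%s]", k, r, r2[pair], prov[pair]
        )

    if config.overall_r2_cs_adj is not None:
        overall = RsqEstimates(
            r2_cs_adj=config.overall_r2_cs_adj,
            max_r2_cs=max_r2_multinomial(dist),
            provenance="reported",
        )
    else:
        overall = RsqEstimates.from_nagelkerke(config.nagelkerke_fallback, dist)
    logger.info(
        "overall: R2_CS_adj = %.4f, max = %.4f [%s]",
        overall.r2_cs_adj,
        overall.max_r2_cs,
        overall.provenance,
    )
    return PairwiseEvidence(r2=r2, provenance=prov, overall=overall)


def run_sizing(config: RunConfig) -> SampleSizeReport:
    """Execute the full six-step sizing workflow for one configuration."""
    dist = config.dist
    cfg = config.sizing
    evidence = resolve_evidence(config)
    crit_i = criterion_i(dist, evidence, cfg)
    crit_ii = criterion_ii(dist.K, cfg, evidence.overall)
    crit_iii = criterion_iii(dist, cfg)
    warnings_: list[str] = []
    # traceability note for the integer rounding of the criterion-(ii) bound
    import math

    r2, mx = evidence.overall.r2_cs_adj, evidence.overall.max_r2_cs
    s_bound = r2 / (r2 + cfg.delta_r2 * mx)
    raw_ii = ((dist.K - 1) * cfg.Q) / (
        (s_bound - 1.0) * math.log(1.0 - r2 - cfg.delta_r2 * mx)
    )
    warnings_.append(
        f"criterion (ii): unrounded bound is {raw_ii:.2f}; the reported n "
        f"({crit_ii.n}) is the smallest integer at or above it under the "
        f"'{cfg.rounding}' policy"
    )
    epv_cmp = (
        {e: epv_size(e, cfg.Q, dist) for e in config.epv} if config.epv else None
    )
    inputs = {
        "counts": list(dist.counts),
        "n_source": dist.n,
        "Q": cfg.Q,
        "S_target": cfg.s_target,
        "S_target_overrides": {f"{k},{r}": v for (k, r), v in cfg.s_target_overrides.items()},
        "delta_r2": cfg.delta_r2,
        "delta_precision": cfg.delta_precision,
        "alpha": cfg.alpha,
        "rounding": cfg.rounding,
        "pointwise": cfg.pointwise,
        "seed": config.seed,
        "pairwise_r2": {f"{k},{r}": v for (k, r), v in evidence.r2.items()},
        "pairwise_provenance": {
            f"{k},{r}": v for (k, r), v in evidence.provenance.items()
        },
        "overall_r2_cs_adj": evidence.overall.r2_cs_adj,
        "overall_max_r2": evidence.overall.max_r2_cs,
        "overall_provenance": evidence.overall.provenance,
    }
    return final_size(
        crit_i,
        crit_ii,
        crit_iii,
        dist,
        inputs=inputs,
        extra_warnings=warnings_,
        epv_comparison=epv_cmp,
    )


def report_to_dict(report: SampleSizeReport) -> dict:
    """Lossless JSON-ready representation of a report."""

    def crit(c: CriterionResult) -> dict:
        return {
            "criterion": c.criterion,
            "n": c.n,
            "per_pair_m": (
                {f"{k},{r}": v for (k, r), v in c.per_pair_m.items()}
                if c.per_pair_m is not None
                else None
            ),
            "per_pair_n": (
                {f"{k},{r}": v for (k, r), v in c.per_pair_n.items()}
                if c.per_pair_n is not None
                else None
            ),
            "per_category_n": (
                {str(k): v for k, v in c.per_category_n.items()}
                if c.per_category_n is not None
                else None
            ),
            "binding": (
                f"{c.binding[0]},{c.binding[1]}"
                if isinstance(c.binding, tuple)
                else c.binding
            ),
            "warnings": list(c.warnings),
        }

    return {
        "criterion_i": crit(report.criterion_i),
        "criterion_ii": crit(report.criterion_ii),
        "criterion_iii": crit(report.criterion_iii),
        "final_n": report.final_n,
        "binding_criterion": report.binding_criterion,
        "expected_counts": list(report.expected_counts),
        "inputs": report.inputs,
        "warnings": list(report.warnings),
        "epv_comparison": (
            {str(e): n for e, n in report.epv_comparison.items()}
            if report.epv_comparison is not None
            else None
        ),
    }


def report_from_dict(data: Mapping) -> SampleSizeReport:
    """Inverse of :func:`report_to_dict`."""

    def crit(d: Mapping) -> CriterionResult:
        def pairs(m):
            if m is None:
                return None
            return {
                tuple(int(x) for x in key.split(",")): v for key, v in m.items()
            }

        binding = d["binding"]
        if isinstance(binding, str) and "," in binding:
            binding = tuple(int(x) for x in binding.split(","))
        return CriterionResult(
            criterion=d["criterion"],
            n=d["n"],
            per_pair_m=pairs(d["per_pair_m"]),
            per_pair_n=pairs(d["per_pair_n"]),
            per_category_n=(
                {int(k): v for k, v in d["per_category_n"].items()}
                if d["per_category_n"] is not None
                else None
            ),
            binding=binding,
            warnings=tuple(d["warnings"]),
        )

    return SampleSizeReport(
        criterion_i=crit(data["criterion_i"]),
        criterion_ii=crit(data["criterion_ii"]),
        criterion_iii=crit(data["criterion_iii"]),
        final_n=data["final_n"],
        binding_criterion=data["binding_criterion"],
        expected_counts=tuple(data["expected_counts"]),
        inputs=dict(data["inputs"]),
        warnings=tuple(data["warnings"]),
        epv_comparison=(
            {float(e): n for e, n in data["epv_comparison"].items()}
            if data["epv_comparison"] is not None
            else None
        ),
    )


def render_report(report: SampleSizeReport, fmt: str = "table") -> str:
    """Render a report as JSON (lossless) or a human-readable table."""
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if fmt != "table":
        raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'table')")

    lines: list[str] = []
    ci = report.criterion_i
    lines.append("Criterion (i): pairwise shrinkage")
    lines.append(f"  {'pair':>6} {'R2_CS':>7} {'m_kr':>9} {'n_kr':>7}  provenance")
    prov = report.inputs.get("pairwise_provenance", {})
    r2s = report.inputs.get("pairwise_r2", {})
    for (k, r), m in sorted(ci.per_pair_m.items()):
        key = f"{k},{r}"
        mark = " <- binding" if (k, r) == ci.binding else ""
        lines.append(
            f"  {key:>6} {r2s.get(key, float('nan')):>7.3f} {m:>9.1f} "
            f"{ci.per_pair_n[(k, r)]:>7d}  {prov.get(key, '?')}{mark}"
        )
    lines.append(f"  criterion (i) n = {ci.n}")
    lines.append("")
    lines.append(f"Criterion (ii): Nagelkerke R2 optimism  n = {report.criterion_ii.n}")
    lines.append("")
    lines.append("Criterion (iii): simultaneous precision of category proportions")
    for k, nk in sorted(report.criterion_iii.per_category_n.items()):
        mark = " <- binding" if k == report.criterion_iii.binding else ""
        lines.append(f"  category {k}: n = {nk}{mark}")
    lines.append(f"  criterion (iii) n = {report.criterion_iii.n}")
    lines.append("")
    lines.append(
        f"Final minimum sample size: n = {report.final_n} "
        f"(binding criterion: {report.binding_criterion})"
    )
    lines.append(
        "Expected events per category at final n: "
        + ", ".join(str(c) for c in report.expected_counts)
    )
    if report.epv_comparison:
        lines.append("")
        lines.append("Events-per-variable comparator (not a recommendation):")
        for e, n in sorted(report.epv_comparison.items()):
            lines.append(f"  EPV {e:g}: n = {n}")
    if report.warnings:
        lines.append("")
        lines.append("Warnings:")
        for w in report.warnings:
            lines.append(f"  - {w}")
    return "\n".join(lines) + "\n"
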