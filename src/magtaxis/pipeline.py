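"""End-to-end assay analyses and JSON reporting.

Two entry points mirror the two assays:

* :func:`magnet_assay_analysis` — per-plate preference indices compared
  across conditions with a two-sided Mann-Whitney U test (magnet vs.
  control and diacetyl vs. control; no multiple-testing adjustment).
* :func:`field_assay_analysis` — applies the plate-inclusion filters, then
  per condition computes each kept plate's mean heading, runs the
  second-order Rayleigh test on the sample of plate mean directions (each
  plate contributing one unit vector), bootstraps a 95% CI for the
  second-order directedness ``r``, and checks whether the zero-field ``r``
  falls inside each magnetic condition's CI.

:func:`render_report` serializes either report to schema-versioned JSON at
full float precision, so identical inputs and seed give a byte-identical
report.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from magtaxis.circular import (
    AngleSample,
    BootstrapCI,
    DirectionalSummary,
    RayleighResult,
    bootstrap_r_ci,
    ci_contains,
    mean_vector,
    rayleigh_test,
)
from magtaxis.data import (
    BalanceResult,
    FieldPlate,
    FilterConfig,
    MagnetPlate,
    PlateExclusion,
    balance_check,
    filter_plates,
)

__all__ = [
    "FieldAssayReport",
    "MagnetAssayReport",
    "MannWhitneyResult",
    "PipelineError",
    "field_assay_analysis",
    "magnet_assay_analysis",
    "mann_whitney_u",
    "preference_index",
    "render_report",
]

SCHEMA_VERSION = "1.0"


class PipelineError(ValueError):
    """Raised when an analysis precondition is not met."""


def preference_index(count_target: int, count_control: int) -> float:
    """Preference index PI = (T - C) / (T + C), in [-1, 1].

    T worms reached the target circle (magnet or attractant), C the control
    circle.  Undefined when no worm reached either circle.
    """
    if count_target < 0 or count_control < 0:
        raise ValueError("counts must be nonnegative")
    total = count_target + count_control
    if total == 0:
        raise ValueError("preference index undefined: no worm reached a circle")
    return (count_target - count_control) / total


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as arrangement counts over 0..n1*n2 (no ties).

    Classic recurrence c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u): the
    largest pooled value is either an x (contributing j to U) or a y.
    Total count is C(n1+n2, n1).
    """
    max_u = n1 * n2
    cur = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        cur[j][0] = 1.0  # no x's: U = 0
    for _i in range(1, n1 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        new[0][0] = 1.0  # no y's: U = 0
        for j in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[j:] = cur[j][: max_u + 1 - j]
            new[j] = shifted + new[j - 1]
        cur = new
    return cur[n2]


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of ``x`` against ``y``.

    Returns the U statistic for ``x`` (number of (x, y) pairs with x > y,
    ties counting one half).  The p-value is exact — by enumeration of the
    null U distribution — when ``min(n1, n2) <= 8`` and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if min(n1, n2) <= 8 and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        k = int(round(u1))
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total  # P(U >= u1), inclusive
        p = min(1.0, 2.0 * min(cdf, sf))
        return MannWhitneyResult(u=u1, p=p, n1=n1, n2=n2, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u=u1, p=1.0, n1=n1, n2=n2, method="asymptotic")
    num = abs(u1 - mu) - 0.5  # continuity correction
    z = max(num, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MannWhitneyResult(u=u1, p=p, n1=n1, n2=n2, method="asymptotic")


@dataclass(frozen=True)
class MagnetAssayReport:
    """Per-condition preference indices and pairwise U-test comparisons."""

    pi_by_condition: dict[str, list[float]]
    comparisons: dict[str, MannWhitneyResult]
    n_dropped_undefined: int

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "assay": "magnet",
            "pi_by_condition": {k: list(v) for k, v in self.pi_by_condition.items()},
            "comparisons": {
                k: {"u": v.u, "p": v.p, "n1": v.n1, "n2": v.n2, "method": v.method}
                for k, v in self.comparisons.items()
            },
            "n_dropped_undefined": self.n_dropped_undefined,
        }


@dataclass(frozen=True)
class FieldConditionResult:
    plate_summaries: list[DirectionalSummary]
    second_order: DirectionalSummary
    rayleigh: RayleighResult
    bootstrap: BootstrapCI


@dataclass(frozen=True)
class FieldAssayReport:
    """Second-order circular analysis of the horizontal-field assay."""

    conditions: dict[str, FieldConditionResult]
    containment: dict[str, dict]
    exclusions: list[PlateExclusion]
    kept_counts: dict[str, int]
    balance: BalanceResult
    seed: int | None
    n_reps: int

    def to_dict(self) -> dict:
        def _summary(s: DirectionalSummary) -> dict:
            return {"n": s.n, "mu_deg": s.mu_deg, "r": s.r}

        return {
            "schema_version": SCHEMA_VERSION,
            "assay": "field",
            "seed": self.seed,
            "bootstrap_reps": self.n_reps,
            "conditions": {
                cond: {
                    "plate_summaries": [_summary(s) for s in res.plate_summaries],
                    "second_order": _summary(res.second_order),
                    "rayleigh": {
                        "n": res.rayleigh.n,
                        "r": res.rayleigh.r,
                        "z": res.rayleigh.z,
                        "p": res.rayleigh.p,
                    },
                    "bootstrap_ci": {
                        "lower": res.bootstrap.lower,
                        "upper": res.bootstrap.upper,
                        "n_reps": res.bootstrap.n_reps,
                        "conf_level": res.bootstrap.conf_level,
                    },
                }
                for cond, res in self.conditions.items()
            },
            "containment": self.containment,
            "filtering": {
                "kept_counts": self.kept_counts,
                "excluded": [
                    {"plate_id": e.plate_id, "condition": e.condition, "reasons": list(e.reasons)}
                    for e in self.exclusions
                ],
            },
            "balance": {
                "counts": self.balance.counts,
                "p_value": self.balance.p_value,
                "balanced": self.balance.balanced,
            },
        }


def magnet_assay_analysis(plates: list[MagnetPlate]) -> MagnetAssayReport:
    """Preference-index analysis of the two-target assay.

    Computes per-plate PIs and compares magnet vs. control and diacetyl vs.
    control with the two-sided Mann-Whitney U test.  Plates where no worm
    reached either circle have no PI and are dropped with a warning.  No
    multiple-testing adjustment is applied.
    """
    if not plates:
        raise PipelineError("no plates to analyze")
    pi: dict[str, list[float]] = {}
    dropped = 0
    for plate in plates:
        if not plate.pi_defined:
            dropped += 1
            continue
        pi.setdefault(plate.condition, []).append(
            preference_index(plate.count_target, plate.count_control)
        )
    if dropped:
        warnings.warn(f"dropped {dropped} plate(s) with undefined preference index", stacklevel=2)
    comparisons: dict[str, MannWhitneyResult] = {}
    if "control" in pi:
        for cond in ("magnet", "diacetyl"):
            if cond in pi:
                comparisons[f"{cond}_vs_control"] = mann_whitney_u(pi[cond], pi["control"])
    return MagnetAssayReport(
        pi_by_condition=pi, comparisons=comparisons, n_dropped_undefined=dropped
    )


def field_assay_analysis(
    plates: list[FieldPlate],
    filters: FilterConfig | None = None,
    n_reps: int = 100_000,
    seed: int | None = None,
) -> FieldAssayReport:
    """Filtered second-order circular analysis of the horizontal-field assay.

    After filtering, each kept plate is reduced to its mean heading; the
    per-condition second-order sample of plate mean directions (one unit
    vector per plate) is tested for uniformity with the Rayleigh test and
    bootstrapped for a 95% CI of its directedness ``r``.  The zero-field
    ``r`` is then checked for containment in each magnetic condition's CI:
    a zero-field ``r`` below a magnetic CI means that magnetic condition is
    significantly more directed (p < 0.05).
    """
    if not plates:
        raise PipelineError("no plates to analyze")
    kept, excluded = filter_plates(plates, filters)
    input_conditions = sorted({p.condition for p in plates})
    kept_by_cond: dict[str, list[FieldPlate]] = {c: [] for c in input_conditions}
    for plate in kept:
        kept_by_cond[plate.condition].append(plate)
    for cond, group in kept_by_cond.items():
        if len(group) < 2:
            raise PipelineError(
                f"condition {cond!r} has {len(group)} kept plate(s); "
                "at least 2 are required for the second-order analysis"
            )

    # one child seed per condition, in stable (sorted) order
    children = np.random.SeedSequence(seed).spawn(len(input_conditions))
    results: dict[str, FieldConditionResult] = {}
    for cond, child in zip(input_conditions, children):
        group = kept_by_cond[cond]
        summaries = [mean_vector(p.headings) for p in group]
        directed = [s for s in summaries if s.mu_defined]
        n_undef = len(summaries) - len(directed)
        if n_undef:
            warnings.warn(
                f"condition {cond!r}: {n_undef} plate(s) with undefined mean "
                "direction excluded from the second-order sample",
                stacklevel=2,
            )
        if len(directed) < 2:
            raise PipelineError(
                f"condition {cond!r} has fewer than 2 plates with a defined mean direction"
            )
        second_sample = AngleSample(np.array([s.mu_deg for s in directed]))
        second = mean_vector(second_sample)
        ray = rayleigh_test(second_sample)
        boot_seed = int(child.generate_state(1)[0] % (2**31))
        ci = bootstrap_r_ci(second_sample, n_reps=n_reps, seed=boot_seed)
        results[cond] = FieldConditionResult(
            plate_summaries=summaries, second_order=second, rayleigh=ray, bootstrap=ci
        )

    containment: dict[str, dict] = {}
    if "zero" in results:
        r_zero = results["zero"].second_order.r
        for cond in input_conditions:
            if cond == "zero":
                continue
            contained, verdict = ci_contains(results[cond].bootstrap, r_zero)
            containment[cond] = {
                "r_zero": r_zero,
                "contained": contained,
                "verdict": verdict,
            }

    kept_counts = {c: len(g) for c, g in kept_by_cond.items()}
    return FieldAssayReport(
        conditions=results,
        containment=containment,
        exclusions=excluded,
        kept_counts=kept_counts,
        balance=balance_check(kept),
        seed=seed,
        n_reps=n_reps,
    )


def render_report(report: MagnetAssayReport | FieldAssayReport, out: str | Path) -> Path:
    """Write a report as schema-versioned JSON at full float precision."""
    from magtaxis import __version__

    doc = report.to_dict()
    doc["software"] = {"name": "magtaxis", "version": __version__}
    out = Path(out)
    out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out
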