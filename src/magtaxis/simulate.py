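"""Hierarchical synthetic data for both plate assays.

The horizontal-field generator mirrors the two statistical commitments of
the assay design: worms on one plate are not independent (so plate mean
directions, not worms, carry the treatment signal), and a magnetotactic
population would prefer a fixed compass direction (~305 deg relative to the
field lines).  Plate mean directions are drawn from a von Mises
distribution around the population direction with concentration
``kappa_between`` (0 = uniform null), and worm headings from a von Mises
around their plate mean with concentration ``kappa_within``.  Environmental
metadata is sampled inside the filter-pass region, except for a designated
fraction of plates that each violate exactly one randomly chosen inclusion
rule.

The two-target generator draws the number of worms reaching the circles
from a truncated Poisson and splits it between target and control circles
with a beta-binomial, whose intra-plate correlation ``rho`` captures the
plate-to-plate overdispersion of preference indices.

A mechanistic correlated-random-walk generator for exit angles is also
provided for studying how heading bias accumulates over a plate crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from magtaxis.circular import AngleSample, rad_to_compass
from magtaxis.data import FIELD_CONDITIONS, EnvMetadata, FieldPlate, MagnetPlate

__all__ = [
    "FieldSimConfig",
    "MagnetSimConfig",
    "simulate_biased_walk",
    "simulate_field_plates",
    "simulate_magnet_plates",
]


def _per_condition(value, condition: str) -> float:
    if isinstance(value, Mapping):
        return float(value[condition])
    return float(value)


@dataclass(frozen=True)
class FieldSimConfig:
    """Parameters of the hierarchical horizontal-field simulation.

    ``n_plates_per_condition`` plates are generated for each condition in
    ``conditions``; ``kappa_between`` and ``kappa_within`` may be a single
    number or a per-condition mapping (e.g. zero-field null plus biased
    magnetic conditions).  Worm counts per plate are Poisson(``worms_per_
    plate_mean``) truncated at >= 1.  ``frac_filter_violations`` of plates
    receive metadata violating exactly one randomly chosen inclusion rule.
    """

    n_plates_per_condition: int | Mapping[str, int] = 26
    worms_per_plate_mean: float = 75.0
    mu_population_deg: float = 305.0
    kappa_between: float | Mapping[str, float] = 0.0
    kappa_within: float | Mapping[str, float] = 1.0
    frac_filter_violations: float = 0.0
    conditions: tuple[str, ...] = FIELD_CONDITIONS
    seed: int | None = None

    def __post_init__(self) -> None:
        for cond in self.conditions:
            if cond not in FIELD_CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if _per_condition(self.kappa_between, cond) < 0:
                raise ValueError("kappa_between must be nonnegative")
            if _per_condition(self.kappa_within, cond) < 0:
                raise ValueError("kappa_within must be nonnegative")
            if _per_condition(self.n_plates_per_condition, cond) < 1:
                raise ValueError("n_plates_per_condition must be at least 1")
        if not 0.0 <= self.frac_filter_violations <= 1.0:
            raise ValueError("frac_filter_violations must lie in [0, 1]")
        if self.worms_per_plate_mean <= 0:
            raise ValueError("worms_per_plate_mean must be positive")


@dataclass(frozen=True)
class MagnetSimConfig:
    """Parameters of the two-target count simulation.

    ``p_target`` is the expected fraction of worms choosing the target
    circle (0.5 = no preference); ``overdispersion_rho`` in [0, 1) is the
    intra-plate correlation of the beta-binomial split (0 = pure binomial).
    """

    n_plates: int = 23
    worms_reaching_mean: float = 60.0
    p_target: float = 0.5
    overdispersion_rho: float = 0.0
    condition: str = "magnet"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise ValueError("n_plates must be at least 1")
        if self.worms_reaching_mean <= 0:
            raise ValueError("worms_reaching_mean must be positive")
        if not 0.0 < self.p_target < 1.0:
            raise ValueError("p_target must lie in (0, 1)")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")


def _vonmises_compass(
    rng: np.random.Generator, mu_deg: float, kappa: float, size: int
) -> np.ndarray:
    """Von Mises draws in compass degrees; exact uniform when kappa == 0."""
    if kappa == 0.0:
        return rng.uniform(0.0, 360.0, size=size)
    draws = rng.vonmises(np.deg2rad(mu_deg), kappa, size=size)
    return rad_to_compass(draws)


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by resampling zeros."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


# Metadata for filter-passing plates is sampled strictly inside the pass
# region; a violating plate breaks exactly one randomly chosen rule.
_PASS_HUMIDITY = (30.0, 49.0)
_PASS_TEMP = (20.0, 23.5)
_PASS_DELTA = 1.4
_PASS_DURATION = (56.0, 64.0)
_VIOLATION_RULES = ("min_worms", "humidity", "temperature", "temp_delta", "duration")


def _passing_env(rng: np.random.Generator) -> EnvMetadata:
    t0 = rng.uniform(*_PASS_TEMP)
    return EnvMetadata(
        humidity_pct=rng.uniform(*_PASS_HUMIDITY),
        temp_start_c=t0,
        temp_end_c=t0 + rng.uniform(-_PASS_DELTA, _PASS_DELTA),
        duration_min=rng.uniform(*_PASS_DURATION),
    )


def _violating_env(rng: np.random.Generator, rule: str) -> EnvMetadata:
    env = _passing_env(rng)
    if rule == "humidity":
        return EnvMetadata(
            rng.uniform(50.0, 70.0), env.temp_start_c, env.temp_end_c, env.duration_min
        )
    if rule == "temperature":
        hot = rng.uniform(25.5, 28.0)
        return EnvMetadata(env.humidity_pct, hot, hot + rng.uniform(-1.0, 1.0), env.duration_min)
    if rule == "temp_delta":
        # downward drift only: an upward drift could also trip the max-temp
        # rule and the plate must violate exactly one
        return EnvMetadata(
            env.humidity_pct,
            env.temp_start_c,
            env.temp_start_c - rng.uniform(2.0, 4.0),
            env.duration_min,
        )
    if rule == "duration":
        bad = rng.uniform(40.0, 54.0) if rng.random() < 0.5 else rng.uniform(66.0, 80.0)
        return EnvMetadata(env.humidity_pct, env.temp_start_c, env.temp_end_c, bad)
    return env  # min_worms violations act on the worm count, not the metadata


def simulate_field_plates(config: FieldSimConfig) -> list[FieldPlate]:
    """Generate horizontal-field plates under the hierarchical model.

    For each plate the plate mean direction is drawn von Mises around the
    population direction (uniform when ``kappa_between`` is 0), then worm
    headings von Mises around the plate mean (uniform when ``kappa_within``
    is 0).  Reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    plates: list[FieldPlate] = []
    for cond in config.conditions:
        n_plates = int(_per_condition(config.n_plates_per_condition, cond))
        kb = _per_condition(config.kappa_between, cond)
        kw = _per_condition(config.kappa_within, cond)
        n_violating = int(round(config.frac_filter_violations * n_plates))
        violating = set(rng.choice(n_plates, size=n_violating, replace=False).tolist())
        for j in range(n_plates):
            mu_plate = float(_vonmises_compass(rng, config.mu_population_deg, kb, 1)[0])
            n_worms = int(_truncated_poisson(rng, config.worms_per_plate_mean, 1)[0])
            rule = None
            if j in violating:
                rule = str(rng.choice(_VIOLATION_RULES))
            if rule == "min_worms":
                n_worms = int(rng.integers(1, 30))
            headings = _vonmises_compass(rng, mu_plate, kw, n_worms)
            env = _violating_env(rng, rule) if rule else _passing_env(rng)
            plates.append(
                FieldPlate(
                    plate_id=f"{cond}-{j + 1:03d}",
                    condition=cond,
                    headings=AngleSample(headings),
                    env=env,
                )
            )
    return plates


def simulate_magnet_plates(config: MagnetSimConfig) -> list[MagnetPlate]:
    """Generate two-target plates: truncated-Poisson totals, beta-binomial split."""
    rng = np.random.default_rng(config.seed)
    totals = _truncated_poisson(rng, config.worms_reaching_mean, config.n_plates)
    p, rho = config.p_target, config.overdispersion_rho
    if rho == 0.0:
        targets = rng.binomial(totals, p)
    else:
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        plate_p = rng.beta(a, b, size=config.n_plates)
        targets = rng.binomial(totals, plate_p)
    return [
        MagnetPlate(
            plate_id=f"{config.condition}-{j + 1:03d}",
            condition=config.condition,
            count_target=int(t),
            count_control=int(n - t),
        )
        for j, (n, t) in enumerate(zip(totals, targets))
    ]


def simulate_biased_walk(
    n_worms: int,
    bias_weight: float,
    target_deg: float,
    step_deg_sd: float,
    plate_radius: float = 50.0,
    seed: int | None = None,
    max_steps: int = 10_000,
) -> AngleSample:
    """Exit angles of correlated random walks with a directional bias.

    Each worm starts at the plate center with a uniform initial heading and
    takes unit-length steps.  At every step the heading receives a
    wrapped-normal turn (SD ``step_deg_sd`` degrees) and is then blended
    toward ``target_deg`` with weight ``bias_weight`` (0 = no bias, exit
    angles uniform; 1 = ballistic toward the target).  The exit angle is
    the compass bearing of the first position at or beyond ``plate_radius``.
    Walks that fail to exit within ``max_steps`` are dropped with a warning.
    """
    if not 0.0 <= bias_weight <= 1.0:
        raise ValueError("bias_weight must lie in [0, 1]")
    if step_deg_sd < 0 or plate_radius <= 0 or n_worms < 1:
        raise ValueError("invalid walk parameters")
    rng = np.random.default_rng(seed)
    target = np.deg2rad(target_deg)
    tx, ty = np.cos(target), np.sin(target)
    exits: list[float] = []
    dropped = 0
    for _ in range(n_worms):
        heading = rng.uniform(0.0, 2.0 * np.pi)
        x = y = 0.0
        for _step in range(max_steps):
            heading += np.deg2rad(rng.normal(0.0, step_deg_sd)) if step_deg_sd > 0 else 0.0
            hx = (1.0 - bias_weight) * np.cos(heading) + bias_weight * tx
            hy = (1.0 - bias_weight) * np.sin(heading) + bias_weight * ty
            norm = np.hypot(hx, hy)
            if norm < 1e-12:  # bias exactly cancels the heading; re-draw turn
                continue
            heading = np.arctan2(hy, hx)
            x += hx / norm
            y += hy / norm
            if np.hypot(x, y) >= plate_radius:
                exits.append(float(rad_to_compass(np.arctan2(y, x))))
                break
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} walk(s) did not reach the plate rim within {max_steps} steps "
            "and were dropped",
            stacklevel=2,
        )
    if not exits:
        raise RuntimeError("no walk reached the plate rim")
    return AngleSample(np.array(exits))
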