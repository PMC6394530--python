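"""Synthetic property tables and labeled benchmarks with known structure.

The generator emulates the statistical shape the desirability model
assumes: unimodal, asymmetric per-property distributions for the actives of
one target. Continuous properties are drawn from a split (two-sided) normal
— mode exactly at the requested value, different left/right standard
deviations so the skewness that motivates the asymmetric sigmoid is present
— and count properties are the same draws rounded and clipped at zero.
Inactive pools reuse the active families with spreads inflated (and
optionally modes shifted) by a separation factor, so class separability is
a controllable ground truth.

Default modes are chemically plausible small-molecule magnitudes for a
screening hit series (MW ~ 269, ALogP ~ 3.4, a couple of aromatic rings).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .desirability import ADSParams, evaluate_ads
from .errors import FixtureError
from .properties import (
    INTEGER_PROPERTIES,
    PROPERTY_NAMES,
    CompoundRecord,
    PropertyVector,
)

__all__ = [
    "PropertySpec", "FixtureSpec", "DEFAULT_PROPERTY_SPECS",
    "generate_actives", "generate_benchmark", "ads_reference_sample",
]


@dataclass(frozen=True)
class PropertySpec:
    """Generating distribution of one property: split-normal(mode, spread, skew).

    ``spread`` is the mean of the left/right standard deviations; ``skew``
    is their ratio sigma_right/sigma_left (1 = symmetric, >1 = right tail).
    """

    mode: float
    spread: float
    skew: float = 1.0

    def __post_init__(self):
        if self.spread <= 0:
            raise FixtureError(f"spread must be positive, got {self.spread}")
        if self.skew <= 0:
            raise FixtureError(f"skew must be positive, got {self.skew}")

    @property
    def sigmas(self) -> tuple[float, float]:
        sigma_l = 2.0 * self.spread / (1.0 + self.skew)
        return sigma_l, self.skew * sigma_l


#: Default active-compound distributions: a plausible small-molecule series.
DEFAULT_PROPERTY_SPECS: dict[str, PropertySpec] = {
    "MW": PropertySpec(mode=269.0, spread=55.0, skew=1.6),
    "ALOGP": PropertySpec(mode=3.4, spread=1.2, skew=1.3),
    "HBD": PropertySpec(mode=1.0, spread=1.2, skew=1.8),
    "HBA": PropertySpec(mode=4.0, spread=1.6, skew=1.4),
    "PSA": PropertySpec(mode=54.0, spread=22.0, skew=1.7),
    "ROTB": PropertySpec(mode=2.5, spread=1.8, skew=1.6),
    "AROM": PropertySpec(mode=2.0, spread=1.3, skew=1.4),
    "ALERTS": PropertySpec(mode=0.0, spread=1.6, skew=2.5),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Full benchmark recipe: per-property families, sizes, separation, seed."""

    properties: dict[str, PropertySpec] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_SPECS))
    n_active: int = 500
    n_inactive: int = 5000
    separation: float = 1.0
    mode_shift: float = 0.0  # inactive modes move this many active spreads
    seed: int = 0

    def __post_init__(self):
        if set(self.properties) != set(PROPERTY_NAMES):
            raise FixtureError(
                f"properties must cover exactly {PROPERTY_NAMES}, "
                f"got {sorted(self.properties)}"
            )
        if self.n_active < 20:
            raise FixtureError(f"n_active must be >= 20, got {self.n_active}")
        if self.separation < 1.0:
            raise FixtureError(f"separation must be >= 1, got {self.separation}")
        for name, ps in self.properties.items():
            if name in INTEGER_PROPERTIES and ps.mode < 0:
                raise FixtureError(f"{name}: integer-property mode must be >= 0")


def _draw_split_normal(rng: np.random.Generator, ps: PropertySpec,
                       n: int) -> np.ndarray:
    """Draws with density proportional to two half-normals glued at the mode."""
    sigma_l, sigma_r = ps.sigmas
    right = rng.random(n) < sigma_r / (sigma_l + sigma_r)
    mag = np.abs(rng.standard_normal(n))
    return ps.mode + np.where(right, mag * sigma_r, -mag * sigma_l)


_MW_FLOOR = 20.0  # keep molecular weights physically sensible


def _finalize(name: str, values: np.ndarray) -> np.ndarray:
    if name in INTEGER_PROPERTIES:
        return np.clip(np.round(values), 0, None)
    if name == "MW":
        return np.clip(values, _MW_FLOOR, None)
    if name == "PSA":
        return np.clip(values, 0.0, None)
    return values


def _generate_table(properties: dict[str, PropertySpec], n: int,
                    rng: np.random.Generator) -> np.ndarray:
    cols = []
    for name in PROPERTY_NAMES:
        cols.append(_finalize(name, _draw_split_normal(rng, properties[name], n)))
    return np.column_stack(cols)


def _to_records(X: np.ndarray, prefix: str, label: Optional[str]) -> list[CompoundRecord]:
    width = len(str(X.shape[0]))
    return [
        CompoundRecord(f"{prefix}{i + 1:0{width}d}",
                       PropertyVector.from_array(row), label)
        for i, row in enumerate(X)
    ]


def generate_actives(spec: FixtureSpec) -> list[CompoundRecord]:
    """``n_active`` synthetic actives; a pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    X = _generate_table(spec.properties, spec.n_active, rng)
    return _to_records(X, "A", "active")


def _inactive_specs(spec: FixtureSpec) -> dict[str, PropertySpec]:
    out = {}
    for name, ps in spec.properties.items():
        mode = ps.mode + spec.mode_shift * ps.spread
        if name in INTEGER_PROPERTIES:
            mode = max(mode, 0.0)
        out[name] = replace(ps, mode=mode, spread=ps.spread * spec.separation)
    return out


def generate_benchmark(spec: FixtureSpec) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """(actives, inactives) with labels attached.

    Inactives come from the same distribution families with spreads
    multiplied by ``separation`` (and modes shifted by ``mode_shift``
    spreads). At separation 1 with no shift the classes are statistically
    identical; separation above 1 makes actives increasingly concentrated
    at the desirability peaks relative to inactives.
    """
    rng = np.random.default_rng(spec.seed)
    A = _generate_table(spec.properties, spec.n_active, rng)
    I = _generate_table(_inactive_specs(spec), spec.n_inactive, rng)
    return _to_records(A, "A", "active"), _to_records(I, "D", "inactive")


def ads_reference_sample(params: ADSParams, n: int, seed: int,
                         support: tuple[float, float]) -> np.ndarray:
    """Rejection-sample ``n`` draws from the normalized ADS curve on ``support``.

    Ground truth for fit-recovery tests: the target density is proportional
    to max(Q(x), 0) restricted to the support interval. Deterministic per
    seed. Raises :class:`FixtureError` if the curve is non-positive there.
    """
    lo, hi = support
    if not hi > lo:
        raise FixtureError(f"empty support {support}")
    grid = np.linspace(lo, hi, 200001)
    envelope = float(np.max(evaluate_ads(grid, params)))
    if envelope <= 0:
        raise FixtureError("ADS curve is non-positive on the stated support")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        m = max(4 * (n - out.size), 1024)
        x = rng.uniform(lo, hi, m)
        u = rng.uniform(0.0, envelope, m)
        y = np.clip(evaluate_ads(x, params), 0.0, None)
        out = np.concatenate([out, x[u <= y]])
    return out[:n]
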