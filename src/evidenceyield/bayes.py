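"""Bayesian point-based adaptation of the ACMG/AMP classification framework.

Evidence codes carry exponentially scaled weights: Supporting = 1 point,
Moderate = 2, Strong = 4, Very Strong = 8 (benign evidence counts negative).
The posterior probability of pathogenicity for a point total ``n`` follows

    posterior odds = O_PVSt ** (n / 8) * prior / (1 - prior)

where ``O_PVSt`` is the odds of pathogenicity assigned to one Very Strong
line of evidence (350 in the published framework).  Class bounds on the point
scale: Pathogenic >= 10, Likely Pathogenic 6..9, VUS 0..5, Likely Benign
-6..-1, Benign <= -7.  At those bounds the defaults give posteriors of ~0.99
(Pathogenic) and ~0.90 (Likely Pathogenic).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import ConfigurationError

_DEFAULT_POINTS = {"Supporting": 1, "Moderate": 2, "Strong": 4, "VeryStrong": 8}
_DEFAULT_BOUNDS = {
    "Pathogenic": (10, math.inf),
    "Likely_Pathogenic": (6, 9),
    "VUS": (0, 5),
    "Likely_Benign": (-6, -1),
    "Benign": (-math.inf, -7),
}

#: Context-specific priors of pathogenicity for a rare missense variant:
#: ~4.5% within curated disease-associated genes, ~1% genome-wide (about
#: five-fold lower, matching the genome's ~5-fold larger gene count).
PRIOR_PRESETS = {"framework": 0.10, "disease_genes": 0.045, "genome_wide": 0.01}


@dataclass(frozen=True)
class Evidence:
    """One applied evidence code, e.g. ``Evidence("PP3", "Strong", "pathogenic")``."""

    code: str
    strength: str
    direction: str = "pathogenic"

    def __post_init__(self) -> None:
        if self.direction not in ("pathogenic", "benign"):
            raise ConfigurationError(f"unknown evidence direction {self.direction!r}")


@dataclass(frozen=True)
class BayesConfig:
    prior: float = 0.10
    odds_very_strong: float = 350.0
    point_values: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_POINTS))
    class_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ConfigurationError(f"prior must lie in (0, 1), got {self.prior}")
        if self.odds_very_strong <= 1.0:
            raise ConfigurationError("odds_very_strong must exceed 1")
        bounds = sorted(self.class_bounds.values())
        for (alo, ahi), (blo, bhi) in zip(bounds, bounds[1:]):
            if ahi >= blo:
                raise ConfigurationError("class_bounds overlap or touch; must partition points")
            if math.isfinite(ahi) and math.isfinite(blo) and blo - ahi != 1:
                raise ConfigurationError("class_bounds leave a gap; must partition integers")


@dataclass(frozen=True)
class CombinationResult:
    total_points: int
    posterior: float
    classification: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.total_points:+d} points -> {self.classification} "
            f"(posterior P(pathogenic) = {self.posterior:.4f})"
        )


def total_points(profile: Sequence[Evidence], cfg: Optional[BayesConfig] = None) -> int:
    """Signed point sum of an evidence profile (benign entries negative).

    PP3-family and BP4-family codes are mutually exclusive for a variant:
    a profile containing both (or two of either) is rejected.
    """
    cfg = cfg or BayesConfig()
    computational = [e for e in profile if e.code in ("PP3", "BP4")]
    if len(computational) > 1:
        raise ConfigurationError(
            "a profile may carry at most one PP3/BP4 entry; got "
            + ", ".join(e.code for e in computational)
        )
    total = 0
    for ev in profile:
        try:
            pts = cfg.point_values[ev.strength]
        except KeyError:
            raise ConfigurationError(f"unknown evidence strength {ev.strength!r}") from None
        total += pts if ev.direction == "pathogenic" else -pts
    return total


def posterior_probability(points: float, cfg: Optional[BayesConfig] = None) -> float:
    """Posterior probability of pathogenicity for a point total."""
    cfg = cfg or BayesConfig()
    prior_odds = cfg.prior / (1.0 - cfg.prior)
    odds = cfg.odds_very_strong ** (points / 8.0) * prior_odds
    return odds / (1.0 + odds)


def classify_combination(points: int, cfg: Optional[BayesConfig] = None) -> CombinationResult:
    """Classification and posterior for a point total under the class bounds."""
    cfg = cfg or BayesConfig()
    for label, (lo, hi) in cfg.class_bounds.items():
        if lo <= points <= hi:
            return CombinationResult(
                total_points=points,
                posterior=posterior_probability(points, cfg),
                classification=label,
            )
    raise ConfigurationError(f"class_bounds do not cover point total {points}")


def combine(profile: Iterable[Evidence], cfg: Optional[BayesConfig] = None) -> CombinationResult:
    """Points -> posterior -> classification for an evidence profile."""
    cfg = cfg or BayesConfig()
    return classify_combination(total_points(list(profile), cfg), cfg)


def parse_codes(spec: str) -> list[Evidence]:
    """Parse ``"PP3:Strong,PM2:Supporting,BS1:Strong:benign"`` into Evidence.

    Direction defaults by code prefix: codes starting with ``B`` count as
    benign, anything else as pathogenic; an explicit third field overrides.
    """
    profile = []
    for chunk in filter(None, (c.strip() for c in spec.split(","))):
        parts = chunk.split(":")
        if len(parts) not in (2, 3):
            raise ConfigurationError(f"cannot parse evidence code {chunk!r}")
        code, strength = parts[0], parts[1]
        direction = parts[2] if len(parts) == 3 else (
            "benign" if code.upper().startswith("B") else "pathogenic"
        )
        profile.append(Evidence(code=code, strength=strength, direction=direction))
    return profile
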