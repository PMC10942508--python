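"""Interval classification of predictor scores into PP3/BP4 evidence strengths.

Each tool has an ordered set of pathogenic-direction breakpoints (score >=
breakpoint grants at least that strength of PP3 evidence) and benign-direction
breakpoints (score <= breakpoint grants BP4 evidence), with an indeterminate
gap between the weakest benign and weakest pathogenic thresholds.  Scores are
compared at full precision; a score equal to a breakpoint takes the stronger
evidence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import pandas as pd
import yaml

from .types import (
    BENIGN_STRENGTHS,
    ConfigurationError,
    DataError,
    NO_SCORE,
    PATHOGENIC_STRENGTHS,
)

_STRENGTH_ORDER = ("Supporting", "Moderate", "Strong", "VeryStrong")


@dataclass(frozen=True)
class ThresholdTable:
    """Calibrated breakpoints for one tool (higher score = more deleterious)."""

    tool: str
    pathogenic: Mapping[str, float]
    benign: Mapping[str, float]
    score_range: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not lo < hi:
            raise ConfigurationError(f"{self.tool}: empty score range {self.score_range}")
        for name, table in (("pathogenic", self.pathogenic), ("benign", self.benign)):
            if not table:
                if name == "pathogenic":
                    raise ConfigurationError(f"{self.tool}: no pathogenic breakpoints")
                continue
            unknown = set(table) - set(_STRENGTH_ORDER)
            if unknown:
                raise ConfigurationError(f"{self.tool}: unknown strengths {sorted(unknown)}")
            present = [s for s in _STRENGTH_ORDER if s in table]
            if present != list(_STRENGTH_ORDER[: len(present)]):
                raise ConfigurationError(
                    f"{self.tool}: {name} strengths must be contiguous from Supporting"
                )
            values = [table[s] for s in present]
            steps = zip(values, values[1:])
            ok = all(a < b for a, b in steps) if name == "pathogenic" else all(
                a > b for a, b in zip(values, values[1:])
            )
            if not ok:
                raise ConfigurationError(
                    f"{self.tool}: {name} breakpoints must be strictly "
                    f"{'increasing' if name == 'pathogenic' else 'decreasing'} with strength"
                )
            for v in values:
                if not (lo <= v <= hi):
                    raise ConfigurationError(
                        f"{self.tool}: breakpoint {v} outside score range {self.score_range}"
                    )
        if self.benign and self.benign["Supporting"] >= self.pathogenic["Supporting"]:
            raise ConfigurationError(
                f"{self.tool}: benign and pathogenic ranges overlap; "
                "no indeterminate interval exists"
            )

    def reachable_categories(self) -> tuple[str, ...]:
        cats = [f"PP3_{s}" for s in PATHOGENIC_STRENGTHS if s in self.pathogenic]
        cats.append("Indeterminate")
        cats += [f"BP4_{s}" for s in reversed(BENIGN_STRENGTHS) if s in self.benign]
        cats.append(NO_SCORE)
        return tuple(cats)


def _default_config_text() -> str:
    return resources.files("evidenceyield.data").joinpath("thresholds.yaml").read_text()


def load_threshold_tables(path: Optional[str] = None) -> dict[str, ThresholdTable]:
    """Load and validate per-tool threshold tables from a YAML config.

    With ``path=None`` the packaged default tables for BayesDel-noAF,
    MutPred2, REVEL and VEST4 are returned — the four metapredictors able to
    reach PP3_Strong and BP4_Moderate under the interval calibration.
    """
    if path is None:
        raw = yaml.safe_load(_default_config_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "tools" not in raw or not raw["tools"]:
        raise ConfigurationError(f"threshold config {path or '<packaged>'} defines no tools")
    tables = {}
    for tool, cfg in raw["tools"].items():
        try:
            tables[tool] = ThresholdTable(
                tool=tool,
                pathogenic=dict(cfg.get("pathogenic") or {}),
                benign=dict(cfg.get("benign") or {}),
                score_range=tuple(cfg["score_range"]),
                source=cfg.get("source", ""),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{tool}: missing required field {exc}") from exc
    return tables


def classify_score(score: Optional[float], table: ThresholdTable) -> str:
    """Map one raw score to its evidence category.

    Missing scores (``None``/NaN) return ``NoScore``.  Otherwise the
    strongest pathogenic strength whose breakpoint the score meets wins; then
    the strongest benign strength; otherwise ``Indeterminate``.  Scores
    outside the declared range raise rather than being clamped.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return NO_SCORE
    lo, hi = table.score_range
    if not (lo <= score <= hi):
        raise DataError(
            f"{table.tool}: score {score} outside declared range [{lo}, {hi}]"
        )
    for strength in PATHOGENIC_STRENGTHS:  # strongest first
        bp = table.pathogenic.get(strength)
        if bp is not None and score >= bp:
            return f"PP3_{strength}"
    for strength in BENIGN_STRENGTHS:
        bp = table.benign.get(strength)
        if bp is not None and score <= bp:
            return f"BP4_{strength}"
    return "Indeterminate"


def classify_variant(scores: Mapping[str, Optional[float]],
                     tables: Mapping[str, ThresholdTable]) -> dict[str, str]:
    """One EvidenceCall per tool; tools without a score yield NoScore."""
    return {tool: classify_score(scores.get(tool), table) for tool, table in tables.items()}


def attach_calls(observations: pd.DataFrame,
                 tables: Mapping[str, ThresholdTable]) -> pd.DataFrame:
    """Add one ``call_<tool>`` column per tool to an observations table.

    Expects one ``score_<tool>`` column per tool (NaN = missing).
    """
    out = observations.copy()
    for tool, table in tables.items():
        col = f"score_{tool}"
        if col not in out.columns:
            out[col] = float("nan")
        out[f"call_{tool}"] = [
            classify_score(None if pd.isna(s) else float(s), table) for s in out[col]
        ]
    return out
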