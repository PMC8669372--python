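"""Rule-based fusion of the two screening channels and wellness indicators.

Each subject gets a PCOS level (P1 high / P2 normal / P3 moderate) and a
mental-health level (M1/M2/M3) from the ranking channel; a total rule base
over the nine (P, M) combinations fuses them into one of four categories:
A1 both conditions, A2 PCOS only, A3 mental-health only, A4 normal.

Two cohort-level indicators quantify comorbidity:

* mental wellness indicator ``I_M`` — of the subjects screened PCOS-positive
  (P1 or P3), the percentage fused into A1;
* physical wellness indicator ``I_P`` — of the subjects screened positive
  for mental-health issues (M1 or M3), the percentage fused into A1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .questionnaire import CATEGORIES, MENTAL_ALTERNATIVES, PHYSICAL_ALTERNATIVES

PCOS_POSITIVE = ("P1", "P3")
MENTAL_POSITIVE = ("M1", "M3")


class RuleBase:
    """Total mapping (P level, M level) → category over all nine combinations."""

    def __init__(self, rules: Sequence[tuple[str, str, str]]):
        table: dict[tuple[str, str], str] = {}
        for p, m, cat in rules:
            if p not in PHYSICAL_ALTERNATIVES:
                raise ValueError(f"unknown PCOS level {p!r}")
            if m not in MENTAL_ALTERNATIVES:
                raise ValueError(f"unknown mental-health level {m!r}")
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if (p, m) in table:
                raise ValueError(f"duplicate rule for ({p}, {m})")
            table[(p, m)] = cat
        missing = [
            (p, m)
            for p in PHYSICAL_ALTERNATIVES
            for m in MENTAL_ALTERNATIVES
            if (p, m) not in table
        ]
        if missing:
            raise ValueError(f"rule base is not total; missing {missing}")
        self._table = table

    def classify(self, p_level: str, m_level: str) -> str:
        if (p_level, m_level) not in self._table:
            raise ValueError(f"no rule for ({p_level!r}, {m_level!r})")
        return self._table[(p_level, m_level)]

    def as_mapping(self) -> Mapping[tuple[str, str], str]:
        return dict(self._table)

    @classmethod
    def default(cls) -> "RuleBase":
        """The nine clinician-validated fusion rules shipped with the package."""
        from .datasets import default_rule_config

        return cls(default_rule_config())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleBase":
        import yaml

        with open(path) as fh:
            return cls([tuple(r) for r in yaml.safe_load(fh)["rules"]])


@dataclass(frozen=True)
class ScreeningResult:
    """Per-subject channel closeness coefficients, levels, and fused category."""

    subject_id: str
    cc_physical: dict[str, float]
    cc_mental: dict[str, float]
    p_level: str
    m_level: str
    category: str


def classify(p_level: str, m_level: str, rules: RuleBase | None = None) -> str:
    """Fuse one subject's channel levels into a category via the rule base."""
    return (rules or RuleBase.default()).classify(p_level, m_level)


def mental_wellness_indicator(results: Sequence[ScreeningResult]) -> float:
    """``I_M``: percentage of PCOS-positive subjects also fused into A1."""
    positive = [r for r in results if r.p_level in PCOS_POSITIVE]
    if not positive:
        raise ValueError("mental wellness indicator undefined: no PCOS-positive subjects")
    both = sum(1 for r in positive if r.category == "A1")
    return 100.0 * both / len(positive)


def physical_wellness_indicator(results: Sequence[ScreeningResult]) -> float:
    """``I_P``: percentage of mental-health-positive subjects also fused into A1."""
    positive = [r for r in results if r.m_level in MENTAL_POSITIVE]
    if not positive:
        raise ValueError("physical wellness indicator undefined: no mental-health-positive subjects")
    both = sum(1 for r in positive if r.category == "A1")
    return 100.0 * both / len(positive)


def write_results_csv(results: Sequence[ScreeningResult], path: str | Path) -> None:
    """Export a screening batch, one row per subject."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["subject_id"]
        header += [f"cc_{a}" for a in PHYSICAL_ALTERNATIVES]
        header += [f"cc_{a}" for a in MENTAL_ALTERNATIVES]
        header += ["p_level", "m_level", "category"]
        w.writerow(header)
        for r in results:
            row = [r.subject_id]
            row += [r.cc_physical[a] for a in PHYSICAL_ALTERNATIVES]
            row += [r.cc_mental[a] for a in MENTAL_ALTERNATIVES]
            row += [r.p_level, r.m_level, r.category]
            w.writerow(row)
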