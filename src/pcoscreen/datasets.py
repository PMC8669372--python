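"""Loaders for the reference data shipped with the package.

Three fixture families come from the instrument's clinical validation
study and let the pipeline run, and be regression-tested, without access
to the original cohort:

* the expert-elicited normalised criterion weights,
* one test subject's per-criterion separation distances to the ideal
  solutions (physical and mental channels), and
* the held-out test-set confusion matrices of the fuzzy screener and the
  SVM baseline, with the channel-level composition of those 167 subjects.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Iterator

import yaml

_DATA = resources.files("pcoscreen") / "data"


def _open(name: str):
    return (_DATA / name).open("r", encoding="utf-8")


def reference_criterion_weights() -> dict[str, float]:
    """Expert-panel normalised weights for the 31 criteria (sum ≈ 0.997)."""
    with _open("criterion_weights.csv") as fh:
        return {row["criterion_id"]: float(row["weight"]) for row in csv.DictReader(fh)}


def reference_separation_tables() -> dict[str, dict[str, dict[str, tuple[float, float]]]]:
    """Worked-example distances ``{channel: {alternative: {criterion: (d*, d−)}}}``."""
    out: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    with _open("reference_distances.csv") as fh:
        for row in csv.DictReader(fh):
            ch = out.setdefault(row["channel"], {})
            alt = ch.setdefault(row["alternative"], {})
            alt[row["criterion"]] = (float(row["d_star"]), float(row["d_minus"]))
    return out


def reference_confusion_matrices() -> dict[str, object]:
    """Validation-study confusion matrices and test-set composition counts."""
    with _open("reference_confusion.yaml") as fh:
        return yaml.safe_load(fh)


def default_rule_config() -> list[tuple[str, str, str]]:
    """The nine clinician-validated fusion rules as (P level, M level, category)."""
    with _open("rule_base.yaml") as fh:
        doc = yaml.safe_load(fh)
    return [tuple(r) for r in doc["rules"]]


def default_instrument_config() -> list[dict]:
    """Raw criterion definitions (id, group, text, ordered answer levels)."""
    with _open("instrument.yaml") as fh:
        return yaml.safe_load(fh)["criteria"]


def iter_reference_profiles() -> Iterator[tuple[str, str, float, float]]:
    """Yield ``(channel, alternative, d_star_total, d_minus_total)`` rows."""
    for channel, alts in reference_separation_tables().items():
        for alt, cells in alts.items():
            yield (
                channel,
                alt,
                sum(v[0] for v in cells.values()),
                sum(v[1] for v in cells.values()),
            )
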