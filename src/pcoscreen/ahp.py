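"""Fuzzy analytic hierarchy process (AHP) for criterion weighting.

Criterion importance is elicited as pairwise comparisons on a Saaty-style
intensity scale whose points carry triangular fuzzy numbers.  Weights are
derived in the classic Buckley fashion: per-row fuzzy geometric means,
fuzzy weights as each mean times the reciprocal of the total, center-of-area
defuzzification, and normalisation so the crisp weights sum to one.

The 31-criterion screening instrument ships a default weight vector elicited
from the clinical expert panel during the instrument's validation study
(:func:`default_weight_vector`); it lets the ranking channel run without a
judgment matrix of one's own.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .fuzzy import TFN, coa_defuzzify, tfn_sum

#: Saaty-style intensities and their fuzzy triples.  Intensity k on the
#: crisp scale carries the triple below; the reverse judgment uses the
#: fuzzy reciprocal.
DEFAULT_AHP_SCALE: dict[str, TFN] = {
    "Equal important": TFN(1, 1, 1),
    "Intermediate (2)": TFN(1, 2, 3),
    "Moderate important": TFN(2, 3, 4),
    "Intermediate (4)": TFN(3, 4, 5),
    "Strong important": TFN(4, 5, 6),
    "Intermediate (6)": TFN(5, 6, 7),
    "Very strong important": TFN(6, 7, 8),
    "Intermediate (8)": TFN(7, 8, 9),
    "Extreme important": TFN(9, 9, 9),
}

#: Random-index table for Saaty's consistency ratio (orders 1..15).
_SAATY_RI = [0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59]


@dataclass(frozen=True)
class ComparisonMatrix:
    """Fuzzy pairwise comparison matrix over named criteria.

    The diagonal is ``(1,1,1)`` and each below-diagonal entry is the fuzzy
    reciprocal of its mirror, both enforced at construction.
    """

    criteria: tuple[str, ...]
    entries: tuple[tuple[TFN, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.criteria)
        if len(self.entries) != n or any(len(row) != n for row in self.entries):
            raise ValueError("comparison matrix must be square over the criteria")
        for i in range(n):
            if self.entries[i][i].as_tuple() != (1.0, 1.0, 1.0):
                raise ValueError(f"diagonal entry for {self.criteria[i]} must be (1,1,1)")
            for j in range(i + 1, n):
                rec = self.entries[i][j].reciprocal()
                mirror = self.entries[j][i]
                if any(abs(x - y) > 1e-9 for x, y in zip(rec.as_tuple(), mirror.as_tuple())):
                    raise ValueError(
                        f"entry ({self.criteria[j]}, {self.criteria[i]}) must be the "
                        f"fuzzy reciprocal of its mirror"
                    )

    @property
    def n(self) -> int:
        return len(self.criteria)


@dataclass(frozen=True)
class WeightVector:
    """Fuzzy, crisp and normalised weights per criterion."""

    criteria: tuple[str, ...]
    fuzzy: tuple[TFN, ...]
    crisp: tuple[float, ...]
    normalized: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.criteria)
        if not (len(self.fuzzy) == len(self.crisp) == len(self.normalized) == k):
            raise ValueError("weight vector fields must align with criteria")
        if any(w < 0 for w in self.normalized):
            raise ValueError("normalized weights must be non-negative")
        if abs(sum(self.normalized) - 1.0) > 1e-9:
            raise ValueError("normalized weights must sum to 1")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.criteria, self.normalized))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["criterion_id", "fuzzy_l", "fuzzy_m", "fuzzy_u", "crisp", "normalized"])
            for cid, f, c, nz in zip(self.criteria, self.fuzzy, self.crisp, self.normalized):
                w.writerow([cid, f.l, f.m, f.u, c, nz])


def build_comparison_matrix(
    judgments: Sequence[tuple[str, str, str]],
    criteria: Sequence[str],
    scale: Mapping[str, TFN] | None = None,
) -> ComparisonMatrix:
    """Assemble a full comparison matrix from one judgment per unordered pair.

    Each judgment ``(ci, cj, label)`` states that criterion ``ci`` relates to
    ``cj`` with the given scale intensity; the mirror entry is filled with
    the fuzzy reciprocal and the diagonal with ``(1,1,1)``.

    Raises
    ------
    ValueError
        On an unknown criterion or scale label, a duplicated pair, or any
        missing pair (the offending pair is named).
    """
    scale = dict(DEFAULT_AHP_SCALE if scale is None else scale)
    crit = tuple(criteria)
    index = {c: k for k, c in enumerate(crit)}
    n = len(crit)
    grid: list[list[TFN | None]] = [[None] * n for _ in range(n)]
    for i in range(n):
        grid[i][i] = TFN(1, 1, 1)
    for ci, cj, label in judgments:
        if ci not in index or cj not in index:
            unknown = ci if ci not in index else cj
            raise ValueError(f"unknown criterion {unknown!r} in judgment ({ci}, {cj})")
        if ci == cj:
            raise ValueError(f"self-comparison for {ci!r} is implicit and may not be supplied")
        if label not in scale:
            raise ValueError(f"unknown scale label {label!r} in judgment ({ci}, {cj})")
        i, j = index[ci], index[cj]
        if grid[i][j] is not None:
            raise ValueError(f"duplicate judgment for pair ({ci}, {cj})")
        grid[i][j] = scale[label]
        grid[j][i] = scale[label].reciprocal()
    missing = [
        (crit[i], crit[j]) for i in range(n) for j in range(i + 1, n) if grid[i][j] is None
    ]
    if missing:
        raise ValueError(f"missing judgments for pairs: {missing}")
    return ComparisonMatrix(crit, tuple(tuple(row) for row in grid))  # type: ignore[arg-type]


def fuzzy_geometric_means(matrix: ComparisonMatrix) -> list[TFN]:
    """Per-row fuzzy geometric mean ``((Πl)^{1/n}, (Πm)^{1/n}, (Πu)^{1/n})``."""
    n = matrix.n
    out = []
    for row in matrix.entries:
        gl = math.prod(e.l for e in row) ** (1.0 / n)
        gm = math.prod(e.m for e in row) ** (1.0 / n)
        gu = math.prod(e.u for e in row) ** (1.0 / n)
        out.append(TFN(gl, gm, gu))
    return out


def fuzzy_weights(geometric_means: Sequence[TFN]) -> list[TFN]:
    """Fuzzy weight per criterion: ``w̃_i = r_i × (Σ_k r_k)^{-1}``."""
    if not geometric_means:
        raise ValueError("at least one geometric mean is required")
    total = tfn_sum(geometric_means)
    if total.l <= 0:
        raise ValueError("sum of geometric means must have a strictly positive support")
    inv = total.reciprocal()
    return [r * inv for r in geometric_means]


def normalized_crisp_weights(
    w_fuzzy: Sequence[TFN], criteria: Sequence[str] | None = None
) -> WeightVector:
    """Defuzzify fuzzy weights by center of area and normalise to sum one."""
    if not w_fuzzy:
        raise ValueError("at least one fuzzy weight is required")
    crisp = [coa_defuzzify(w) for w in w_fuzzy]
    total = sum(crisp)
    if total <= 0:
        raise ValueError("crisp weights sum to zero; cannot normalise")
    names = tuple(criteria) if criteria is not None else tuple(f"C{k+1}" for k in range(len(w_fuzzy)))
    return WeightVector(
        criteria=names,
        fuzzy=tuple(w_fuzzy),
        crisp=tuple(crisp),
        normalized=tuple(c / total for c in crisp),
    )


def derive_weights(matrix: ComparisonMatrix) -> WeightVector:
    """Run the full chain: geometric means → fuzzy weights → normalised crisp."""
    return normalized_crisp_weights(fuzzy_weights(fuzzy_geometric_means(matrix)), matrix.criteria)


def consistency_ratio(matrix: ComparisonMatrix) -> float:
    """Saaty consistency ratio of the COA-defuzzified matrix (optional check).

    Not part of the screening procedure; offered for auditing judgment
    matrices.  Orders 1–2 are perfectly consistent by construction.
    """
    import numpy as np

    n = matrix.n
    if n <= 2:
        return 0.0
    if n > len(_SAATY_RI):
        raise ValueError(f"consistency ratio undefined for n > {len(_SAATY_RI)}")
    crisp = np.array([[coa_defuzzify(e) for e in row] for row in matrix.entries])
    eigvals = np.linalg.eigvals(crisp)
    lam_max = max(eigvals.real)
    ci = (lam_max - n) / (n - 1)
    return float(ci / _SAATY_RI[n - 1])


def load_judgments(path: str | Path) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Read pairwise judgments from a YAML config.

    Expected layout::

        criteria: [C11, C12, ...]
        judgments:
          - [C11, C12, "Moderate important"]
          - ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    criteria = [str(c) for c in doc["criteria"]]
    judgments = [(str(a), str(b), str(lab)) for a, b, lab in doc["judgments"]]
    return judgments, criteria


def default_weight_vector() -> WeightVector:
    """The instrument's default normalised criterion weights.

    Elicited from the expert panel (two gynecologists, one psychologist)
    during the instrument's clinical validation; the printed weights sum to
    0.997 from rounding and are renormalised here so downstream code sees an
    exact unit sum.  Fuzzy components are degenerate since only the crisp
    normalised weights were published.
    """
    from .datasets import reference_criterion_weights

    raw = reference_criterion_weights()
    total = sum(raw.values())
    criteria = tuple(raw)
    normalized = tuple(v / total for v in raw.values())
    return WeightVector(
        criteria=criteria,
        fuzzy=tuple(TFN.crisp(v) for v in raw.values()),
        crisp=tuple(raw.values()),
        normalized=normalized,
    )
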