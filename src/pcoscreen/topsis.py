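"""Fuzzy TOPSIS ranking of diagnosis alternatives.

TOPSIS (Technique for Order of Preference by Similarity to Ideal Solution)
ranks alternatives by simultaneous closeness to a fuzzy positive ideal
solution (FPIS) and remoteness from a fuzzy negative ideal solution (FNIS).
Here the alternatives are the three severity levels of one screening
channel — high / normal / moderate PCOS (P1/P2/P3) or mental-health issues
(M1/M2/M3) — scored on that channel's criteria with triangular fuzzy
ratings and AHP-derived weights.

Pipeline per subject-channel: aggregate multi-rater ratings (min/mean/max),
linearly normalise each criterion by its column's largest upper bound,
multiply by the criterion weight, locate FPIS/FNIS, accumulate vertex
distances, and form closeness coefficients ``CC = d− / (d* + d−)``.  The
alternative with the largest CC is the channel's selected level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .fuzzy import TFN, vertex_distance

#: Linguistic relevance labels for criterion importance.
WEIGHT_SCALE: dict[str, TFN] = {
    "VLR": TFN(0, 0, 2),
    "LR": TFN(2, 3, 4),
    "R": TFN(4, 5, 6),
    "HR": TFN(6, 7, 8),
    "VHR": TFN(8, 9, 10),
}

#: Linguistic rating labels for alternatives.
RATING_SCALE: dict[str, TFN] = {
    "VL": TFN(0, 0, 0.2),
    "L": TFN(0.2, 0.3, 0.4),
    "M": TFN(0.4, 0.5, 0.6),
    "H": TFN(0.6, 0.7, 0.8),
    "VH": TFN(0.8, 0.9, 1.0),
}


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives × criteria grid of fuzzy ratings with per-criterion weights."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    ratings: tuple[tuple[TFN, ...], ...]  # [alternative][criterion]
    weights: tuple[TFN, ...]

    def __post_init__(self) -> None:
        if len(self.ratings) != len(self.alternatives):
            raise ValueError("one rating row per alternative required")
        if any(len(row) != len(self.criteria) for row in self.ratings):
            raise ValueError("every rating row must cover all criteria")
        if len(self.weights) != len(self.criteria):
            raise ValueError("one weight per criterion required")


@dataclass(frozen=True)
class IdealSolutions:
    """Per-criterion FPIS (max upper bound) and FNIS (min lower bound)."""

    fpis: tuple[float, ...]
    fnis: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fpis) != len(self.fnis):
            raise ValueError("FPIS and FNIS must align")
        if any(p < n for p, n in zip(self.fpis, self.fnis)):
            raise ValueError("FPIS must dominate FNIS on every criterion")


@dataclass(frozen=True)
class SeparationProfile:
    """Per-alternative separations from the ideals and closeness coefficients."""

    alternatives: tuple[str, ...]
    d_star: tuple[float, ...]
    d_minus: tuple[float, ...]
    cc: tuple[float, ...] | None = None

    def to_csv(self, path: str | Path) -> None:
        order = rank_alternatives(self) if self.cc is not None else list(self.alternatives)
        ranks = {a: k + 1 for k, a in enumerate(order)}
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["alternative", "d_star", "d_minus", "cc", "rank"])
            for k, a in enumerate(self.alternatives):
                cc = "" if self.cc is None else self.cc[k]
                w.writerow([a, self.d_star[k], self.d_minus[k], cc, ranks.get(a, "")])


def _minmeanmax(cells: Sequence[TFN]) -> TFN:
    return TFN(
        min(c.l for c in cells),
        sum(c.m for c in cells) / len(cells),
        max(c.u for c in cells),
    )


def aggregate_ratings(per_rater: Sequence[Sequence[Sequence[TFN]]]) -> list[list[TFN]]:
    """Fuse K raters' rating grids cell-wise by (min lower, mean mode, max upper)."""
    if not per_rater:
        raise ValueError("at least one rater grid is required")
    shape = (len(per_rater[0]), len(per_rater[0][0]) if per_rater[0] else 0)
    for g in per_rater:
        if (len(g), len(g[0]) if g else 0) != shape:
            raise ValueError("all rater grids must share a shape")
    rows, cols = shape
    return [
        [_minmeanmax([g[i][j] for g in per_rater]) for j in range(cols)]
        for i in range(rows)
    ]


def aggregate_weights(per_rater: Sequence[Sequence[TFN]]) -> list[TFN]:
    """Fuse K raters' fuzzy weight vectors per criterion by (min, mean, max)."""
    if not per_rater:
        raise ValueError("at least one rater weight vector is required")
    n = len(per_rater[0])
    if any(len(v) != n for v in per_rater):
        raise ValueError("all weight vectors must share a length")
    return [_minmeanmax([v[j] for v in per_rater]) for j in range(n)]


def normalize_matrix(dm: DecisionMatrix) -> DecisionMatrix:
    """Linear scale transformation: divide each column by its max upper bound.

    All criteria are treated as benefit criteria (larger rating = stronger
    evidence for the alternative), so only the benefit form is used.
    """
    norm_cols = []
    for j, cid in enumerate(dm.criteria):
        cmax = max(row[j].u for row in dm.ratings)
        if cmax <= 0:
            raise ValueError(f"criterion {cid!r} has a non-positive column maximum")
        norm_cols.append(cmax)
    ratings = tuple(
        tuple(TFN(cell.l / norm_cols[j], cell.m / norm_cols[j], cell.u / norm_cols[j])
              for j, cell in enumerate(row))
        for row in dm.ratings
    )
    return replace(dm, ratings=ratings)


def weight_matrix(dm: DecisionMatrix) -> DecisionMatrix:
    """Multiply each normalised cell component-wise by its criterion weight."""
    ratings = tuple(
        tuple(cell * dm.weights[j] for j, cell in enumerate(row)) for row in dm.ratings
    )
    return replace(dm, ratings=ratings)


def ideal_solutions(dm: DecisionMatrix) -> IdealSolutions:
    """FPIS per criterion = max upper bound over alternatives; FNIS = min lower."""
    if len(dm.alternatives) < 2:
        raise ValueError("ideal solutions need at least two alternatives "
                         "(a sole alternative has zero distance to both ideals)")
    fpis = tuple(max(row[j].u for row in dm.ratings) for j in range(len(dm.criteria)))
    fnis = tuple(min(row[j].l for row in dm.ratings) for j in range(len(dm.criteria)))
    return IdealSolutions(fpis, fnis)


def separation_distances(dm: DecisionMatrix, ideals: IdealSolutions) -> SeparationProfile:
    """Sum vertex distances from each alternative's cells to the promoted ideals."""
    if len(ideals.fpis) != len(dm.criteria):
        raise ValueError("ideals must align with the decision matrix criteria")
    d_star, d_minus = [], []
    for row in dm.ratings:
        d_star.append(sum(vertex_distance(cell, TFN.crisp(p))
                          for cell, p in zip(row, ideals.fpis)))
        d_minus.append(sum(vertex_distance(cell, TFN.crisp(n))
                           for cell, n in zip(row, ideals.fnis)))
    return SeparationProfile(dm.alternatives, tuple(d_star), tuple(d_minus))


def closeness_coefficients(profile: SeparationProfile) -> SeparationProfile:
    """Fill ``CC_i = d−_i / (d*_i + d−_i)`` for every alternative."""
    cc = []
    for a, ds, dn in zip(profile.alternatives, profile.d_star, profile.d_minus):
        total = ds + dn
        if total <= 0:
            raise ValueError(f"degenerate configuration: d* + d− = 0 for {a!r}")
        cc.append(dn / total)
    return replace(profile, cc=tuple(cc))


def rank_alternatives(profile: SeparationProfile) -> list[str]:
    """Alternatives in decreasing CC order; ties broken by declared order."""
    if profile.cc is None:
        raise ValueError("closeness coefficients must be computed before ranking")
    order = {a: k for k, a in enumerate(profile.alternatives)}
    return sorted(profile.alternatives, key=lambda a: (-profile.cc[order[a]], order[a]))


def rank_channel(dm: DecisionMatrix) -> tuple[SeparationProfile, list[str]]:
    """Run normalisation → weighting → ideals → distances → CC → ranking."""
    weighted = weight_matrix(normalize_matrix(dm))
    profile = closeness_coefficients(
        separation_distances(weighted, ideal_solutions(weighted))
    )
    return profile, rank_alternatives(profile)
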