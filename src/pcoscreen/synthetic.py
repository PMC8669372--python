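"""Synthetic labelled cohorts with controllable class structure.

The original screening cohort (624 young adult women, four expert-assigned
categories) is not public, so every pipeline stage is exercised on
generated cohorts instead.  Subjects are drawn label-first from class
priors; answers are then drawn independently per criterion from
class-conditional categorical distributions.  A single ``separation``
scalar interpolates those distributions between uniform noise (0) and
deterministic one-hot answers (1), where the one-hot target encodes the
category's clinical profile: A1 subjects are maximally symptomatic on both
channels, A2 only on the physical items, A3 only on the psychological
items, and A4 on neither.

What this emulates — class-conditional answer tendencies strong enough to
drive ranking, balancing and fusion.  What it does not — real answer
correlations within a subject, ordinal adjacency structure, or realistic
prevalence; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .questionnaire import CATEGORIES, Instrument, SubjectResponse, decode_ordinal

#: Which channels are symptomatic per category: (physical, mental).
_PROFILE = {
    "A1": (True, True),
    "A2": (True, False),
    "A3": (False, True),
    "A4": (False, False),
}

#: Study-condition defaults: the cohort size of the original data
#: collection and equal priors over the four categories.
DEFAULT_N = 624
DEFAULT_PRIORS = (0.25, 0.25, 0.25, 0.25)
DEFAULT_SEPARATION = 0.8


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort."""

    n: int = DEFAULT_N
    class_priors: tuple[float, float, float, float] = DEFAULT_PRIORS
    separation: float = DEFAULT_SEPARATION
    seed: int = 0
    response_model: dict[str, dict[str, np.ndarray]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if len(self.class_priors) != len(CATEGORIES):
            raise ValueError("one prior per category required")
        if any(p < 0 for p in self.class_priors) or abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must be non-negative and sum to 1")
        if not (0.0 <= self.separation <= 1.0):
            raise ValueError("separation must lie in [0, 1]")


def default_response_model(
    separation: float, instrument: Instrument | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Class-conditional answer distributions at the given separation.

    For each category and criterion the distribution is
    ``separation · one_hot(target) + (1 − separation) · uniform`` where the
    target level is the most symptomatic level when the criterion's channel
    is symptomatic for that category and the least symptomatic otherwise.
    """
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must lie in [0, 1]")
    instrument = instrument or Instrument.default()
    model: dict[str, dict[str, np.ndarray]] = {}
    for cat in CATEGORIES:
        phys_sympt, ment_sympt = _PROFILE[cat]
        per_crit: dict[str, np.ndarray] = {}
        for c in instrument.criteria:
            nlev = len(c.levels)
            symptomatic = phys_sympt if c.group == "physical" else ment_sympt
            onehot = np.zeros(nlev)
            onehot[-1 if symptomatic else 0] = 1.0
            per_crit[c.id] = separation * onehot + (1.0 - separation) * np.full(nlev, 1.0 / nlev)
        model[cat] = per_crit
    return model


def generate_cohort(
    spec: CohortSpec = CohortSpec(), instrument: Instrument | None = None
) -> list[SubjectResponse]:
    """Draw a labelled cohort of ``spec.n`` subjects, reproducibly per seed."""
    instrument = instrument or Instrument.default()
    model = spec.response_model or default_response_model(spec.separation, instrument)
    for cat, per_crit in model.items():
        for cid, p in per_crit.items():
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid distribution for ({cat}, {cid})")
            if len(p) != len(instrument[cid].levels):
                raise ValueError(f"distribution length mismatch for ({cat}, {cid})")
    rng = np.random.default_rng(spec.seed)
    label_idx = rng.choice(len(CATEGORIES), size=spec.n, p=np.asarray(spec.class_priors))
    matrix = np.empty((spec.n, len(instrument)), dtype=np.int64)
    for j, cid in enumerate(instrument.ids):
        # per-class inverse-CDF draw keeps the whole column vectorised
        u = rng.random(spec.n)
        for k, cat in enumerate(CATEGORIES):
            mask = label_idx == k
            if not mask.any():
                continue
            cdf = np.cumsum(np.asarray(model[cat][cid], dtype=float))
            matrix[mask, j] = np.searchsorted(cdf, u[mask], side="right").clip(0, len(cdf) - 1)
    return decode_ordinal(matrix, label_idx, instrument)
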