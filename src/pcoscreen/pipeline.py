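"""End-to-end orchestration: screening, baselines, and evaluation.

Per subject the fuzzy track runs one TOPSIS ranking per channel — the
physical items against P1/P2/P3, the psychological items against
M1/M2/M3 — using the expert AHP weights (crisp weights promoted to
degenerate TFNs) and the rating map, selects each channel's top-ranked
level, and fuses the pair through the rule base.  When expert labels are
present, the confusion matrix, accuracy and wellness indicators are
computed against them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .ahp import WeightVector, default_weight_vector
from .fuzzy import TFN
from .metrics import ConfusionMatrix, accuracy, confusion_matrix
from .questionnaire import (
    CATEGORIES,
    Instrument,
    RatingMap,
    SubjectResponse,
    encode_ordinal,
    responses_to_ratings,
)
from .rules import (
    RuleBase,
    ScreeningResult,
    mental_wellness_indicator,
    physical_wellness_indicator,
)
from .topsis import DecisionMatrix, rank_channel

logger = logging.getLogger("pcoscreen")


@dataclass
class ScreeningConfig:
    """Everything a fuzzy screening run needs besides the cohort itself."""

    instrument: Instrument = field(default_factory=Instrument.default)
    weights: WeightVector = field(default_factory=default_weight_vector)
    rating_map: RatingMap | None = None
    rules: RuleBase = field(default_factory=RuleBase.default)

    def __post_init__(self) -> None:
        if self.rating_map is None:
            self.rating_map = RatingMap.monotone_default(self.instrument)


def screen_subject(subject: SubjectResponse, config: ScreeningConfig | None = None) -> ScreeningResult:
    """Run both channel rankings and rule fusion for one subject."""
    config = config or ScreeningConfig()
    weight_of = config.weights.as_mapping()
    cc, levels = {}, {}
    for channel in ("physical", "mental"):
        alts, crit_ids, grid = responses_to_ratings(
            subject, channel, config.rating_map, config.instrument
        )
        dm = DecisionMatrix(
            alternatives=alts,
            criteria=crit_ids,
            ratings=tuple(tuple(row) for row in grid),
            weights=tuple(TFN.crisp(weight_of[c]) for c in crit_ids),
        )
        profile, order = rank_channel(dm)
        cc[channel] = dict(zip(profile.alternatives, profile.cc))
        levels[channel] = order[0]
    return ScreeningResult(
        subject_id=subject.subject_id,
        cc_physical=cc["physical"],
        cc_mental=cc["mental"],
        p_level=levels["physical"],
        m_level=levels["mental"],
        category=config.rules.classify(levels["physical"], levels["mental"]),
    )


def screen_cohort(
    subjects: Sequence[SubjectResponse], config: ScreeningConfig | None = None
) -> tuple[list[ScreeningResult], dict]:
    """Screen every subject; evaluate against expert labels when present.

    Returns ``(results, metrics)``; metrics is empty (with a logged
    warning) when no subject carries a label.
    """
    config = config or ScreeningConfig()
    results = [screen_subject(s, config) for s in subjects]
    logger.info("screened %d subjects", len(results))
    labelled = [(s, r) for s, r in zip(subjects, results) if s.expert_label is not None]
    if not labelled:
        logger.warning("no expert labels present; skipping evaluation metrics")
        return results, {}
    cm = confusion_matrix(
        [s.expert_label for s, _ in labelled], [r.category for _, r in labelled]
    )
    metrics = {"confusion_matrix": cm, "accuracy": accuracy(cm)}
    try:
        metrics["I_M"] = mental_wellness_indicator(results)
    except ValueError:
        logger.warning("I_M undefined: no PCOS-positive subjects")
    try:
        metrics["I_P"] = physical_wellness_indicator(results)
    except ValueError:
        logger.warning("I_P undefined: no mental-health-positive subjects")
    return results, metrics


def run_baseline(
    subjects: Sequence[SubjectResponse],
    model: str = "svm",
    seed: int = 0,
    instrument: Instrument | None = None,
    train_fraction: float = 0.8,
    balance_k: int = 5,
    **hyperparams,
) -> tuple[list[str], ConfusionMatrix, float]:
    """Split → balance(train) → fit → predict(test) → evaluate.

    Returns ``(predicted labels, confusion matrix, accuracy %)`` over the
    held-out test partition.  Balancing touches the training rows only.
    """
    from .baselines import BalancerSpec, SplitSpec, knn_balance, stratified_split, train_and_predict

    instrument = instrument or Instrument.default()
    if any(s.expert_label is None for s in subjects):
        raise ValueError("baseline training requires a fully labelled cohort")
    X, y = encode_ordinal(subjects, instrument)
    X_tr, X_te, y_tr, y_te, _, _ = stratified_split(
        X, y, SplitSpec(train_fraction=train_fraction, seed=seed)
    )
    logger.info("split: %d train / %d test", len(y_tr), len(y_te))
    X_bal, y_bal = knn_balance(X_tr, y_tr, BalancerSpec(k=balance_k, seed=seed))
    logger.info("balanced training rows: %d -> %d", len(y_tr), len(y_bal))
    pred = train_and_predict(X_bal, y_bal, X_te, model=model, seed=seed, **hyperparams)
    actual = [CATEGORIES[i] for i in y_te]
    predicted = [CATEGORIES[i] for i in pred]
    cm = confusion_matrix(actual, predicted)
    return predicted, cm, accuracy(cm)


def run_manifest(config_doc: dict, seed: int | None = None) -> dict:
    """Machine-readable provenance for a run: config hash, seed, versions."""
    import numpy, sklearn

    blob = json.dumps(config_doc, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "pcoscreen": __version__,
            "numpy": numpy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def write_manifest(path: str | Path, config_doc: dict, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(run_manifest(config_doc, seed), fh, indent=2, sort_keys=True)
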