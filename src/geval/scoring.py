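"""Fine and coarse annotation-consistency scores.

The *fine consistency* score of a genome is the percentage of strongly
predictable roles whose annotated multiplicity matches the jackknife
prediction exactly; the *coarse consistency* score is the percentage whose
presence/absence matches.  Both are computed over the same converged
reliable-role set, so an exact match implies a presence match and
coarse >= fine always holds.  Roles annotated in the genome but absent from
the training role universe carry no predictor; they are excluded from the
scores but counted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .genome import AnnotatedGenome, RoleSet
from .matrix import count_roles
from .training import ConsistencyPredictor

__all__ = [
    "ConsistencyResult",
    "fine_consistency",
    "coarse_consistency",
    "score_counts",
    "score_genome",
]


@dataclass
class ConsistencyResult:
    """Consistency scores plus the per-role evidence behind them."""

    fine_consistency: float
    coarse_consistency: float
    predicted: dict[str, int]
    annotated: dict[str, int]
    mismatches: list[tuple[str, int, int]] = field(default_factory=list)
    n_unscored_roles: int = 0  # genome roles outside the training universe

    def to_dict(self) -> dict:
        return {
            "fine_consistency": self.fine_consistency,
            "coarse_consistency": self.coarse_consistency,
            "predicted": dict(self.predicted),
            "annotated": dict(self.annotated),
            "mismatches": [list(m) for m in self.mismatches],
            "n_unscored_roles": self.n_unscored_roles,
        }


def _check_maps(annotated: Mapping[str, int], predicted: Mapping[str, int]) -> list[str]:
    roles = list(predicted.keys())
    if not roles:
        raise ValueError("cannot score an empty role set")
    missing = [r for r in roles if r not in annotated]
    if missing:
        raise ValueError(f"annotated counts missing {len(missing)} scored role(s)")
    return roles


def fine_consistency(
    annotated: Mapping[str, int], predicted: Mapping[str, int]
) -> float:
    """Percentage of scored roles with an exact multiplicity match."""
    roles = _check_maps(annotated, predicted)
    hits = sum(1 for r in roles if int(annotated[r]) == int(predicted[r]))
    return 100.0 * hits / len(roles)


def coarse_consistency(
    annotated: Mapping[str, int], predicted: Mapping[str, int]
) -> float:
    """Percentage of scored roles whose presence/absence matches."""
    roles = _check_maps(annotated, predicted)
    hits = sum(
        1 for r in roles if (int(annotated[r]) > 0) == (int(predicted[r]) > 0)
    )
    return 100.0 * hits / len(roles)


def score_counts(
    predictor: ConsistencyPredictor,
    counts: Mapping[str, int],
    n_unscored_roles: int = 0,
) -> ConsistencyResult:
    """Score a genome given its role-multiplicity mapping.

    Roles in ``counts`` outside the predictor's universe are ignored for
    prediction and reflected in ``n_unscored_roles``.
    """
    universe = set(predictor.reliable_roles_)
    known = {r: int(c) for r, c in counts.items() if r in universe}
    extra = sum(1 for r in counts if r not in universe)
    annotated = {r: known.get(r, 0) for r in predictor.reliable_roles_}
    pred_frame = predictor.predict(
        pd.DataFrame([annotated]), ignore_unknown=True
    )
    predicted = {r: int(v) for r, v in pred_frame.iloc[0].items()}
    mismatches = [
        (r, predicted[r], annotated[r])
        for r in predictor.reliable_roles_
        if predicted[r] != annotated[r]
    ]
    return ConsistencyResult(
        fine_consistency=fine_consistency(annotated, predicted),
        coarse_consistency=coarse_consistency(annotated, predicted),
        predicted=predicted,
        annotated=annotated,
        mismatches=mismatches,
        n_unscored_roles=n_unscored_roles + extra,
    )


def score_genome(
    predictor: ConsistencyPredictor, genome: AnnotatedGenome
) -> ConsistencyResult:
    """Score an annotated genome against a trained predictor set."""
    universe = predictor.reliable_roles_
    role_set = RoleSet(universe)
    vector = count_roles(genome, role_set)
    counts = dict(zip(universe, (int(v) for v in vector)))
    unscored = len({r for r in genome.roles() if r not in set(universe)})
    return score_counts(predictor, counts, n_unscored_roles=unscored)
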