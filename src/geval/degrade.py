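"""Simulated genome degradation and fully synthetic annotated corpora.

Degradation acts directly on role-multiplicity vectors, mirroring how an
annotation-level quality score perceives a damaged genome: incompleteness
lowers a percentage of randomly selected role counts by one (selection
without replacement over the whole role vector; zero counts are unchanged),
and contamination increments a percentage of role counts drawn with
replacement (a role drawn twice gains two).  "A percentage of role counts"
is read as a percentage of the role-vector length, zeros included.

The synthetic corpus generator emulates the structure the consistency
predictors exploit: block-correlated role multiplicities from latent
subsystems (a genome either carries a whole subsystem or none of it),
independent noise roles with unpredictable counts, and near-universal
single-copy roles per taxonomic grouping for marker derivation.  Genomes
are emitted as full :class:`~geval.genome.AnnotatedGenome` objects with
contigs and coordinates so report generation can run end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Contig, Feature, RoleSet
from .matrix import RoleMultiplicityMatrix
from .scoring import fine_consistency
from .training import ConsistencyPredictor

__all__ = [
    "DegradationSpec",
    "SyntheticCorpusSpec",
    "simulate_incompleteness",
    "simulate_contamination",
    "degrade_matrix",
    "degradation_experiment",
    "generate_synthetic_corpus",
    "train_validation_split",
]

#: the pheS alpha-chain role used for "good seed" classification
PHES_ROLE = "Phenylalanyl-tRNA synthetase alpha chain"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation condition."""

    incompleteness_pct: float = 0.0
    contamination_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("incompleteness_pct", "contamination_pct"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {value}")


def simulate_incompleteness(
    counts: np.ndarray, pct: float, rng: np.random.Generator
) -> np.ndarray:
    """Decrement a random ``pct`` of role counts by one (zeros unchanged).

    ``round(pct/100 * n_roles)`` distinct roles are selected uniformly
    without replacement; each selected role with a positive count loses
    exactly one copy.  Counts never increase and never go negative.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    out = np.asarray(counts, dtype=int).copy()
    n_select = _round_half_up(pct / 100.0 * out.size)
    if n_select == 0:
        return out
    chosen = rng.choice(out.size, size=n_select, replace=False)
    positive = chosen[out[chosen] > 0]
    out[positive] -= 1
    return out


def simulate_contamination(
    counts: np.ndarray, pct: float, rng: np.random.Generator
) -> np.ndarray:
    """Increment role counts for ``pct`` draws taken with replacement.

    ``round(pct/100 * n_roles)`` draws are made uniformly with replacement;
    each draw adds one copy of the drawn role, so the vector total grows by
    exactly the number of draws and a role drawn twice gains two.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    out = np.asarray(counts, dtype=int).copy()
    n_draws = _round_half_up(pct / 100.0 * out.size)
    if n_draws == 0:
        return out
    draws = rng.choice(out.size, size=n_draws, replace=True)
    np.add.at(out, draws, 1)
    return out


def degrade_matrix(
    matrix: pd.DataFrame,
    incompleteness_pct: float,
    contamination_pct: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Degrade each genome row independently (incompleteness, then contamination)."""
    values = matrix.to_numpy()
    degraded = np.empty_like(values)
    for i in range(matrix.shape[0]):
        row = simulate_incompleteness(values[i], incompleteness_pct, rng)
        row = simulate_contamination(row, contamination_pct, rng)
        degraded[i] = row
    return pd.DataFrame(degraded, index=matrix.index, columns=matrix.columns)


def train_validation_split(
    matrix: RoleMultiplicityMatrix, validation_fraction: float = 0.20, seed: int = 0
) -> tuple[RoleMultiplicityMatrix, RoleMultiplicityMatrix]:
    """Seeded 80/20 genome split for the degradation experiments."""
    ids = np.asarray(matrix.genome_ids, dtype=object)
    order = np.argsort(ids, kind="stable")
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(len(ids))]
    n_val = _round_half_up(validation_fraction * len(ids))
    val_rows = np.sort(shuffled[:n_val])
    train_rows = np.sort(shuffled[n_val:])
    train = RoleMultiplicityMatrix(
        matrix.data.iloc[train_rows].copy(), role_set=matrix.role_set
    )
    val = RoleMultiplicityMatrix(
        matrix.data.iloc[val_rows].copy(), role_set=matrix.role_set
    )
    return train, val


def degradation_experiment(
    predictor: ConsistencyPredictor,
    validation: RoleMultiplicityMatrix,
    grid: Sequence[tuple[float, float]],
    n_seeds: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Fine consistency and prediction stability under simulated degradation.

    For each (incompleteness %, contamination %) grid point and each seed,
    every validation genome's multiplicity vector is degraded, predictions
    are recomputed from the degraded vector, and two quantities are
    measured per genome: the fine consistency of the degraded annotation
    against its own predictions, and the fraction of role predictions
    identical to the undegraded prediction.  Results are aggregated as
    mean and standard deviation per condition.  The (0, 0) point is exact:
    no randomness is consumed, so it reproduces the undegraded baseline.
    """
    overlap = set(validation.genome_ids) & set(predictor.training_genome_ids_)
    if overlap:
        raise ValueError(
            f"{len(overlap)} genome(s) appear in both the training and "
            f"validation sets, e.g. {sorted(overlap)[:3]}"
        )
    reliable = predictor.reliable_roles_
    annotated0 = validation.data[reliable]
    baseline_pred = predictor.predict(annotated0)
    rows = []
    for inc_pct, cont_pct in grid:
        fine_scores: list[float] = []
        unchanged: list[float] = []
        for s in range(n_seeds):
            seed = np.random.SeedSequence(
                [int(base_seed), int(round(inc_pct * 100)),
                 int(round(cont_pct * 100)), s]
            )
            rng = np.random.default_rng(seed)
            degraded = degrade_matrix(annotated0, inc_pct, cont_pct, rng)
            pred = predictor.predict(degraded)
            match = degraded.to_numpy() == pred.to_numpy()
            fine_scores.extend(100.0 * match.mean(axis=1))
            stable = pred.to_numpy() == baseline_pred.to_numpy()
            unchanged.extend(100.0 * stable.mean(axis=1))
        rows.append(
            {
                "incompleteness_pct": inc_pct,
                "contamination_pct": cont_pct,
                "mean_fine_consistency": float(np.mean(fine_scores)),
                "sd_fine_consistency": float(np.std(fine_scores, ddof=1))
                if len(fine_scores) > 1
                else 0.0,
                "mean_pct_predictions_unchanged": float(np.mean(unchanged)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Conditions of the synthetic annotated corpus.

    Defaults describe a 300-genome corpus in three equal species-level
    groupings with 20 latent subsystems of 10 roles each, 100 independent
    noise roles (multiplicity uniform on {0..5}), and 20 near-universal
    single-copy roles per grouping (single copy in ~98% of each grouping,
    with the exceptions split between deletion and duplication).
    """

    n_genomes: int = 300
    n_subsystems: int = 20
    roles_per_subsystem: int = 10
    subsystem_presence_prob: float = 0.7
    duplication_prob: float = 0.02
    n_noise_roles: int = 100
    n_universal_roles: int = 20
    grouping_sizes: tuple[int, ...] = (100, 100, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_genomes,
            self.n_subsystems,
            self.roles_per_subsystem,
            self.n_universal_roles,
        ) < 1 or self.n_noise_roles < 0:
            raise ValueError("corpus spec counts must be positive")
        for p in (self.subsystem_presence_prob, self.duplication_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.grouping_sizes) != self.n_genomes:
            raise ValueError(
                f"grouping sizes {self.grouping_sizes} must sum to "
                f"n_genomes={self.n_genomes}"
            )


@dataclass
class CorpusLabels:
    """Ground-truth labels of a generated corpus."""

    structured_roles: list[str]
    noise_roles: list[str]
    universal_roles: list[str]
    subsystem_of: dict[str, int]
    role_set: RoleSet
    true_counts: pd.DataFrame
    grouping_of: dict[str, str]  # genome id -> species-level taxon

    @property
    def predictable_roles(self) -> list[str]:
        """Roles predictable by construction: structured plus universal."""
        return self.structured_roles + self.universal_roles


_FEATURE_LENGTH_BP = 1500
_FEATURE_GAP_BP = 100
_CONTIGS_PER_GENOME = 4


def _role_names(spec: SyntheticCorpusSpec) -> tuple[list[str], list[str], list[str]]:
    structured = [
        f"Subsystem {s} role {r}"
        for s in range(spec.n_subsystems)
        for r in range(spec.roles_per_subsystem)
    ]
    noise = [f"Variable element protein {i}" for i in range(spec.n_noise_roles)]
    universal = [PHES_ROLE] + [
        f"Universal housekeeping protein {i}"
        for i in range(1, spec.n_universal_roles)
    ]
    return structured, noise, universal


def _universal_states(
    spec: SyntheticCorpusSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-genome counts (0, 1 or 2) of each universal role, by grouping.

    Within each grouping, each universal role is single-copy in all but
    ``floor(0.02 * size)`` genomes; the exceptional genomes alternate
    between deletion (count 0) and duplication (count 2), keeping the
    exactly-once fraction at >= 98% by construction.
    """
    n_univ = spec.n_universal_roles
    states = np.ones((spec.n_genomes, n_univ), dtype=int)
    offset = 0
    for size in spec.grouping_sizes:
        n_exceptions = int(math.floor(0.02 * size))
        for u in range(n_univ):
            if n_exceptions == 0:
                continue
            rows = offset + rng.choice(size, size=n_exceptions, replace=False)
            for k, row in enumerate(rows):
                states[row, u] = 0 if k % 2 == 0 else 2
        offset += size
    return states


def generate_synthetic_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[AnnotatedGenome], CorpusLabels]:
    """Generate a reproducible annotated corpus with known structure.

    Each genome activates each subsystem independently with
    ``subsystem_presence_prob``; an active subsystem contributes one PEG
    per member role, duplicated (one extra PEG) with ``duplication_prob``
    and capped at multiplicity 5.  Noise-role multiplicities are uniform
    on {0..5}, independent of everything.  Universal roles are single-copy
    in >= 97% of each grouping by construction (see
    :func:`_universal_states`); the first universal role is the pheS alpha
    chain, emitted with an in-range protein length so seed classification
    is exercised.  Contigs and coordinates are emitted for every feature.
    """
    structured, noise, universal = _role_names(spec)
    all_roles = structured + noise + universal
    role_set = RoleSet(all_roles)
    rng = np.random.default_rng(spec.seed)

    active = rng.random((spec.n_genomes, spec.n_subsystems)) < spec.subsystem_presence_prob
    n_struct = len(structured)
    struct_counts = np.repeat(active.astype(int), spec.roles_per_subsystem, axis=1)
    duplicated = (
        rng.random((spec.n_genomes, n_struct)) < spec.duplication_prob
    ) & (struct_counts > 0)
    struct_counts = np.minimum(struct_counts + duplicated.astype(int), 5)
    noise_counts = rng.integers(0, 6, size=(spec.n_genomes, spec.n_noise_roles))
    universal_counts = _universal_states(spec, rng)
    counts = np.hstack([struct_counts, noise_counts, universal_counts])

    lineages: list[list[str]] = []
    grouping_of: dict[str, str] = {}
    genome_ids: list[str] = []
    g = 0
    for gi, size in enumerate(spec.grouping_sizes):
        family = f"fam{gi // 2}"  # adjacent groupings share a family
        genus = f"gen{gi}"
        species = f"sp{gi}"
        for _ in range(size):
            genome_id = f"G{g:04d}"
            genome_ids.append(genome_id)
            lineages.append([family, genus, species])
            grouping_of[genome_id] = species
            g += 1

    genomes = [
        _build_genome(genome_ids[i], lineages[i], all_roles, counts[i])
        for i in range(spec.n_genomes)
    ]
    true_counts = pd.DataFrame(counts, index=genome_ids, columns=all_roles)
    labels = CorpusLabels(
        structured_roles=structured,
        noise_roles=noise,
        universal_roles=universal,
        subsystem_of={
            role: s
            for s in range(spec.n_subsystems)
            for role in structured[
                s * spec.roles_per_subsystem : (s + 1) * spec.roles_per_subsystem
            ]
        },
        role_set=role_set,
        true_counts=true_counts,
        grouping_of=grouping_of,
    )
    return genomes, labels


def _build_genome(
    genome_id: str, lineage: list[str], roles: list[str], counts: np.ndarray
) -> AnnotatedGenome:
    pegs = [role for role, n in zip(roles, counts) for _ in range(int(n))]
    per_contig = max(1, -(-len(pegs) // _CONTIGS_PER_GENOME))  # ceil division
    span = _FEATURE_LENGTH_BP + _FEATURE_GAP_BP
    contig_len = per_contig * span + _FEATURE_GAP_BP
    contigs = [
        Contig(contig_id=f"{genome_id}.c{c}", length=contig_len)
        for c in range(_CONTIGS_PER_GENOME)
    ]
    features = []
    for i, role in enumerate(pegs):
        contig = contigs[i // per_contig]
        slot = i % per_contig
        start = _FEATURE_GAP_BP + slot * span + 1
        end = start + _FEATURE_LENGTH_BP - 1
        features.append(
            Feature(
                feature_id=f"{genome_id}.peg.{i}",
                contig_id=contig.contig_id,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                function=role,
                # pheS gets an in-range alpha-chain length (209-405 aa for
                # bacteria) so seed-quality classification is exercised
                protein_length=350 if role == PHES_ROLE else _FEATURE_LENGTH_BP // 3 - 1,
            )
        )
    return AnnotatedGenome(
        genome_id=genome_id,
        name=f"Synthetic organism {genome_id}",
        domain="bacteria",
        lineage=lineage,
        contigs=contigs,
        features=features,
    )
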