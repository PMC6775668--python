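"""Role-multiplicity matrices and training-matrix construction.

The central data structure is a genomes x roles matrix of non-negative
integer multiplicities (the number of PEGs implementing each role in each
genome).  Training matrices are built from annotated genomes by counting
roles and applying three filters: keep roles that (1) belong to subsystems,
(2) occur in at least a minimum fraction of training genomes, and (3) never
exceed a maximum multiplicity in any training genome — the last excludes
mobile-element roles with highly variable counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, RoleSet

__all__ = [
    "RoleMultiplicityMatrix",
    "MatrixParseError",
    "EmptyMatrixError",
    "count_roles",
    "genomes_to_matrix",
    "build_training_matrix",
    "filter_training_matrix",
    "read_matrix",
    "write_matrix",
]

logger = logging.getLogger(__name__)


class MatrixParseError(ValueError):
    """A matrix file contained a malformed cell."""


class EmptyMatrixError(ValueError):
    """All roles were removed by the training filters."""


class RoleMultiplicityMatrix:
    """Genomes x roles matrix of non-negative integer role multiplicities.

    Thin wrapper over a pandas DataFrame (index = genome ids, columns =
    role names) that enforces integrality and non-negativity.  ``dropped``
    records roles removed by training filters, mapping each to the names of
    the filters it violated.
    """

    def __init__(self, data: pd.DataFrame, role_set: RoleSet | None = None) -> None:
        values = data.to_numpy()
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise MatrixParseError(
                f"negative multiplicity at genome {data.index[bad[0]]!r}, "
                f"role {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(int)
        self.role_set = role_set if role_set is not None else RoleSet(list(data.columns))
        self.dropped: dict[str, list[str]] = {}

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def roles(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, genome_id: str) -> pd.Series:
        return self.data.loc[genome_id]

    def restrict(self, roles: Sequence[str]) -> "RoleMultiplicityMatrix":
        """Return a copy with columns restricted to ``roles`` (kept in order)."""
        sub = RoleSet(list(roles), subsystem_roles=self.role_set.subsystem_roles)
        return RoleMultiplicityMatrix(self.data[list(roles)].copy(), role_set=sub)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RoleMultiplicityMatrix)
            and self.data.equals(other.data)
        )


def count_roles(genome: AnnotatedGenome, role_set: RoleSet) -> np.ndarray:
    """Multiplicity of each role of ``role_set`` in ``genome``.

    Entry ``r`` is the number of PEGs whose function contains role ``r``;
    a PEG with a multi-role function contributes one count to each of its
    roles.  Roles absent from the genome get 0.
    """
    if len(role_set) == 0:
        raise ValueError("role_set must be non-empty")
    counts = np.zeros(len(role_set), dtype=int)
    for role in genome.roles():
        if role in role_set:
            counts[role_set.index(role)] += 1
    return counts


def genomes_to_matrix(
    genomes: Sequence[AnnotatedGenome], role_set: RoleSet
) -> RoleMultiplicityMatrix:
    """Stack :func:`count_roles` vectors into a matrix, one row per genome."""
    rows = [count_roles(g, role_set) for g in genomes]
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(role_set)), dtype=int),
        index=[g.genome_id for g in genomes],
        columns=list(role_set),
    )
    return RoleMultiplicityMatrix(data, role_set=role_set)


def filter_training_matrix(
    matrix: RoleMultiplicityMatrix,
    min_prevalence: float = 0.10,
    max_multiplicity: int = 5,
) -> RoleMultiplicityMatrix:
    """Apply the three training-role filters to an existing matrix.

    A role is retained iff it is a subsystem member, is non-zero in at
    least ``min_prevalence`` of the genomes (closed bound), and its
    multiplicity never exceeds ``max_multiplicity`` in any genome.  The
    filters are independent per role, hence order-independent.  Dropped
    roles are recorded on the result's ``dropped`` attribute and logged.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genomes to build a training matrix")
    prevalence = (matrix.data > 0).mean(axis=0)
    max_mult = matrix.data.max(axis=0) if matrix.shape[0] else None
    retained: list[str] = []
    dropped: dict[str, list[str]] = {}
    for role in matrix.roles:
        violated = []
        if not matrix.role_set.is_subsystem_member(role):
            violated.append("not_in_subsystem")
        if prevalence[role] < min_prevalence:
            violated.append("prevalence")
        if max_mult[role] > max_multiplicity:
            violated.append("max_multiplicity")
        if violated:
            dropped[role] = violated
            logger.debug("dropping role %r: %s", role, ",".join(violated))
        else:
            retained.append(role)
    if not retained:
        raise EmptyMatrixError(
            f"all {len(matrix.roles)} roles removed by the training filters"
        )
    logger.info(
        "training matrix: retained %d/%d roles (%d dropped)",
        len(retained), len(matrix.roles), len(dropped),
    )
    result = matrix.restrict(retained)
    result.dropped = dropped
    return result


def build_training_matrix(
    genomes: Sequence[AnnotatedGenome],
    role_set: RoleSet,
    min_prevalence: float = 0.10,
    max_multiplicity: int = 5,
) -> RoleMultiplicityMatrix:
    """Count roles across ``genomes`` and apply the training filters."""
    return filter_training_matrix(
        genomes_to_matrix(genomes, role_set),
        min_prevalence=min_prevalence,
        max_multiplicity=max_multiplicity,
    )


def read_matrix(
    path: str | Path, subsystem_roles: Iterable[str] | None = None
) -> RoleMultiplicityMatrix:
    """Read a multiplicity matrix from TSV.

    Layout: header row of role names, first column genome ids, cells
    tab-separated non-negative integer multiplicities (the layout of
    published multiplicity-matrix supplements).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise MatrixParseError(
                f"{path}: cell at genome {row!r}, role {col!r} is not a "
                f"non-negative integer: {df.loc[row, col]!r}"
            )
        df[col] = numeric.astype(int)
    role_set = RoleSet(list(df.columns), subsystem_roles=subsystem_roles)
    return RoleMultiplicityMatrix(df, role_set=role_set)


def write_matrix(matrix: RoleMultiplicityMatrix, path: str | Path) -> None:
    """Write a multiplicity matrix as TSV (lossless round trip)."""
    matrix.data.to_csv(path, sep="\t")
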