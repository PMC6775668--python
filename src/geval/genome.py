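"""Genome data model and I/O.

The annotation model follows RAST/SEED conventions.  A genome is a set of
contigs plus protein-encoding gene (PEG) features, each carrying a free-text
*function*.  A function is composed of one or more *roles* drawn from a
controlled vocabulary; multifunctional proteins separate their roles with
``" / "`` (fusion), ``" @ "`` (ambiguous assignment) or ``"; "`` (alternative
assignments), and a trailing ``" # ..."`` is a curator comment.  The exact
separator grammar is a convention of this package (see ``docs/methods.md``);
it matches common SEED annotation practice but annotation sources vary.

Two on-disk formats are supported:

* ``geval-json`` -- the native JSON dialect (one object per genome, schema in
  ``docs/genome-schema.md``), lossless for every field of the model;
* GFF3 plus a two-column TSV mapping feature id to function string, because
  free-text functions do not survive GFF3 attribute escaping reliably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "AnnotatedGenome",
    "Contig",
    "Feature",
    "RoleSet",
    "GenomeParseError",
    "GenomeValidationError",
    "function_to_roles",
    "parse_genome",
    "write_genome",
]

#: multi-role separators, applied in this order (space-sensitive)
ROLE_SEPARATORS = (" / ", " @ ", "; ")
#: a curator comment is everything after this marker
COMMENT_MARKER = " # "

Domain = Literal["bacteria", "archaea"]
VALID_DOMAINS = ("bacteria", "archaea")


class GenomeParseError(ValueError):
    """A genome file did not conform to its declared dialect."""


class GenomeValidationError(ValueError):
    """A structurally well-formed genome violated a model invariant."""


def function_to_roles(function: str | None) -> list[str]:
    """Split a functional annotation into its constituent roles.

    Curator comments (``" # ..."``) are stripped first, then the text is
    split on the multi-role separators.  Whitespace around each role is
    removed and empty fragments are dropped, so an empty or comment-only
    function yields an empty list.  The operation is idempotent on its own
    output: every returned role maps back to ``[role]``.
    """
    if not function:
        return []
    text = function.split(COMMENT_MARKER, 1)[0]
    parts = [text]
    for sep in ROLE_SEPARATORS:
        parts = [piece for part in parts for piece in part.split(sep)]
    return [role for role in (p.strip() for p in parts) if role]


@dataclass
class Contig:
    """A contiguous assembled sequence, known here only by id and length."""

    contig_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GenomeValidationError(
                f"contig {self.contig_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass
class Feature:
    """A protein-encoding gene with 1-based inclusive coordinates."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    function: str
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.protein_length is not None and self.protein_length < 1:
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: protein_length must be positive"
            )

    def roles(self) -> list[str]:
        return function_to_roles(self.function)


@dataclass
class AnnotatedGenome:
    """An annotated genome: contigs, PEG features and a taxonomic lineage.

    ``lineage`` is ordered most general to most specific (e.g. family,
    genus, species) and must be non-empty; marker-set selection walks it
    from the specific end.
    """

    genome_id: str
    name: str
    domain: Domain
    lineage: list[str]
    contigs: list[Contig] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.domain not in VALID_DOMAINS:
            raise GenomeValidationError(
                f"genome {self.genome_id!r}: domain must be one of {VALID_DOMAINS}, "
                f"got {self.domain!r}"
            )
        if not self.lineage:
            raise GenomeValidationError(
                f"genome {self.genome_id!r}: lineage must be non-empty"
            )
        lengths = {c.contig_id: c.length for c in self.contigs}
        if len(lengths) != len(self.contigs):
            raise GenomeValidationError(
                f"genome {self.genome_id!r}: duplicate contig ids"
            )
        for f in self.features:
            if f.contig_id not in lengths:
                raise GenomeValidationError(
                    f"feature {f.feature_id!r} references unknown contig {f.contig_id!r}"
                )
            if f.end > lengths[f.contig_id]:
                raise GenomeValidationError(
                    f"feature {f.feature_id!r}: end={f.end} exceeds contig "
                    f"{f.contig_id!r} length {lengths[f.contig_id]}"
                )

    def roles(self) -> list[str]:
        """All role occurrences, one entry per (PEG, role) pair."""
        return [role for f in self.features for role in f.roles()]

    def features_for_role(self, role: str) -> list[Feature]:
        return [f for f in self.features if role in f.roles()]


class RoleSet:
    """An ordered role vocabulary with stable column indices.

    Each role optionally carries a subsystem-membership flag; roles are
    subsystem members by default unless ``subsystem_roles`` is given.
    """

    def __init__(
        self,
        roles: Sequence[str],
        subsystem_roles: Iterable[str] | None = None,
    ) -> None:
        self.roles: list[str] = list(roles)
        if len(set(self.roles)) != len(self.roles):
            raise GenomeValidationError("role names must be unique")
        self._index: dict[str, int] = {r: i for i, r in enumerate(self.roles)}
        if subsystem_roles is None:
            self._subsystem = set(self.roles)
        else:
            self._subsystem = set(subsystem_roles) & set(self.roles)

    def __len__(self) -> int:
        return len(self.roles)

    def __iter__(self):
        return iter(self.roles)

    def __contains__(self, role: str) -> bool:
        return role in self._index

    def index(self, role: str) -> int:
        return self._index[role]

    def is_subsystem_member(self, role: str) -> bool:
        return role in self._subsystem

    @property
    def subsystem_roles(self) -> set[str]:
        return set(self._subsystem)


# ---------------------------------------------------------------------------
# geval-json dialect
# ---------------------------------------------------------------------------

def _genome_to_dict(genome: AnnotatedGenome) -> dict:
    return {
        "genome_id": genome.genome_id,
        "name": genome.name,
        "domain": genome.domain,
        "lineage": list(genome.lineage),
        "contigs": [
            {"contig_id": c.contig_id, "length": c.length} for c in genome.contigs
        ],
        "features": [
            {
                "feature_id": f.feature_id,
                "contig_id": f.contig_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "function": f.function,
                "protein_length": f.protein_length,
            }
            for f in genome.features
        ],
    }


def _genome_from_dict(doc: Mapping, source: str = "<dict>") -> AnnotatedGenome:
    try:
        contigs = [
            Contig(contig_id=str(c["contig_id"]), length=int(c["length"]))
            for c in doc.get("contigs", [])
        ]
        features = [
            Feature(
                feature_id=str(f["feature_id"]),
                contig_id=str(f["contig_id"]),
                start=int(f["start"]),
                end=int(f["end"]),
                strand=str(f["strand"]),
                function=str(f.get("function", "")),
                protein_length=(
                    int(f["protein_length"])
                    if f.get("protein_length") is not None
                    else None
                ),
            )
            for f in doc.get("features", [])
        ]
        return AnnotatedGenome(
            genome_id=str(doc["genome_id"]),
            name=str(doc.get("name", "")),
            domain=doc["domain"],
            lineage=[str(t) for t in doc["lineage"]],
            contigs=contigs,
            features=features,
        )
    except KeyError as exc:
        raise GenomeParseError(f"{source}: missing required field {exc}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, GenomeValidationError):
            raise
        raise GenomeParseError(f"{source}: malformed value ({exc})") from exc


def write_genome(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a genome in the native JSON dialect."""
    with open(path, "w") as fh:
        json.dump(_genome_to_dict(genome), fh, indent=1)
        fh.write("\n")


def parse_genome(
    path: str | Path,
    format: str = "geval-json",
    *,
    functions_path: str | Path | None = None,
    genome_id: str | None = None,
    name: str = "",
    domain: Domain = "bacteria",
    lineage: Sequence[str] | None = None,
) -> AnnotatedGenome:
    """Parse a genome file in one of the supported dialects.

    ``geval-json`` is self-contained.  ``gff3+functions-tsv`` additionally
    requires ``functions_path`` (TSV: feature id, function, optional protein
    length) and the metadata absent from GFF3 (``genome_id``, ``domain``,
    ``lineage``).
    """
    if format == "geval-json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GenomeParseError(
                f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}"
            ) from exc
        return _genome_from_dict(doc, source=str(path))
    if format == "gff3+functions-tsv":
        if functions_path is None or lineage is None:
            raise ValueError(
                "gff3+functions-tsv requires functions_path and lineage"
            )
        return _parse_gff3(
            path,
            functions_path,
            genome_id=genome_id or Path(path).stem,
            name=name,
            domain=domain,
            lineage=list(lineage),
        )
    raise ValueError(f"unknown genome format {format!r}")


def _read_functions_tsv(path: str | Path) -> dict[str, tuple[str, int | None]]:
    table: dict[str, tuple[str, int | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GenomeParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            plen: int | None = None
            if len(fields) >= 3 and fields[2]:
                try:
                    plen = int(fields[2])
                except ValueError as exc:
                    raise GenomeParseError(
                        f"{path}:{lineno}: protein length {fields[2]!r} is not an integer"
                    ) from exc
            table[fields[0]] = (fields[1], plen)
    return table


def _parse_gff3(
    gff_path: str | Path,
    functions_path: str | Path,
    *,
    genome_id: str,
    name: str,
    domain: Domain,
    lineage: list[str],
) -> AnnotatedGenome:
    import gffutils

    functions = _read_functions_tsv(functions_path)
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types for bad input
        raise GenomeParseError(f"{gff_path}: GFF3 parse failed ({exc})") from exc

    contigs: list[Contig] = []
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            fields = directive.split()
            if len(fields) != 4:
                raise GenomeParseError(
                    f"{gff_path}: malformed directive '##{directive}'"
                )
            contigs.append(Contig(contig_id=fields[1], length=int(fields[3])))
    if not contigs:
        raise GenomeParseError(
            f"{gff_path}: no ##sequence-region directives (contig lengths required)"
        )

    features: list[Feature] = []
    for rec in db.features_of_type("CDS", order_by=("seqid", "start")):
        fid = rec.id
        function, plen = functions.get(fid, ("", None))
        features.append(
            Feature(
                feature_id=fid,
                contig_id=rec.seqid,
                start=rec.start,
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                function=function,
                protein_length=plen,
            )
        )
    return AnnotatedGenome(
        genome_id=genome_id,
        name=name,
        domain=domain,
        lineage=lineage,
        contigs=contigs,
        features=features,
    )
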