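"""Genome quality reports.

A quality report combines the marker-based completeness/contamination
scores, the fine/coarse consistency scores, the good / good-seed
classification, and a *problematic roles* table: one row per reliable role
whose predicted and annotated multiplicities disagree, with a structured
comment explaining why the role may be problematic (universal-role status,
the contigs carrying the implementing features, short-contig /
near-contig-edge / short-feature flags, and — for missing roles — the
features implementing the role in a reference genome, when one is given).

Classification thresholds (all closed bounds):

* good: contamination <= 10, fine consistency >= 87, completeness >= 80;
* good seed: exactly one pheS alpha-chain PEG of appropriate length
  (209-405 amino-acid residues for bacteria, 293-652 for archaea).

Reports render as JSON (lossless round trip), TSV (one row per genome:
genome id, name, fine consistency, completeness, contamination, Good,
Good Seed) and plain structured HTML with the five-column problematic
roles table.  External viewer hyperlinks are replaced by plain feature and
contig identifiers unless a URL template is configured.
"""

from __future__ import annotations

import html as _html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .genome import AnnotatedGenome, Feature
from .markers import EvalGResult, MarkerRoleSet
from .scoring import ConsistencyResult

__all__ = [
    "ReportConfig",
    "ProblematicRole",
    "QualityReport",
    "PHES_ROLE",
    "GOOD_CONTAMINATION_MAX",
    "GOOD_FINE_CONSISTENCY_MIN",
    "GOOD_COMPLETENESS_MIN",
    "PHES_LENGTH_RANGES",
    "build_problematic_roles",
    "contigs_without_reliable_roles",
    "classify_genome",
    "find_phes_features",
    "build_quality_report",
    "render_report",
    "render_batch_tsv",
    "parse_report_json",
]

logger = logging.getLogger(__name__)

PHES_ROLE = "Phenylalanyl-tRNA synthetase alpha chain"

GOOD_CONTAMINATION_MAX = 10.0
GOOD_FINE_CONSISTENCY_MIN = 87.0
GOOD_COMPLETENESS_MIN = 80.0

#: acceptable pheS alpha-chain protein lengths (aa), closed ranges
PHES_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "bacteria": (209, 405),
    "archaea": (293, 652),
}

TSV_COLUMNS = [
    "Genome ID",
    "Genome Name",
    "Fine Consistency",
    "Completeness",
    "Contamination",
    "Good",
    "Good Seed",
]


@dataclass(frozen=True)
class ReportConfig:
    """Thresholds for the structured comment flags.

    The flags themselves are standard; these specific thresholds are this
    package's defaults and are deliberately configurable.
    """

    short_contig_bp: int = 1000
    edge_distance_bp: int = 5
    short_feature_fraction: float = 0.5
    #: optional template like "https://example/view/{feature_id}"
    url_template: str | None = None


@dataclass
class ProblematicRole:
    """One row of the problematic-roles table."""

    role: str
    predicted_count: int
    annotated_count: int
    feature_ids: list[str]
    comment: str

    def __post_init__(self) -> None:
        if self.predicted_count == self.annotated_count:
            raise ValueError(
                f"role {self.role!r} is not problematic "
                f"(predicted == annotated == {self.predicted_count})"
            )
        if (self.annotated_count == 0) != (not self.feature_ids):
            raise ValueError(
                f"role {self.role!r}: feature list must be empty exactly "
                f"when the annotated count is zero"
            )

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "predicted_count": self.predicted_count,
            "annotated_count": self.annotated_count,
            "feature_ids": list(self.feature_ids),
            "comment": self.comment,
        }


@dataclass
class QualityReport:
    """The full quality report for one genome."""

    genome_id: str
    name: str
    completeness: float
    contamination: float
    fine_consistency: float
    coarse_consistency: float
    good: bool
    good_seed: bool
    grouping_used: str
    problematic_roles: list[ProblematicRole] = field(default_factory=list)
    contigs_without_reliable_roles: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "name": self.name,
            "completeness": self.completeness,
            "contamination": self.contamination,
            "fine_consistency": self.fine_consistency,
            "coarse_consistency": self.coarse_consistency,
            "good": self.good,
            "good_seed": self.good_seed,
            "grouping_used": self.grouping_used,
            "problematic_roles": [p.to_dict() for p in self.problematic_roles],
            "contigs_without_reliable_roles": list(
                self.contigs_without_reliable_roles
            ),
        }


# ---------------------------------------------------------------------------
# problematic roles
# ---------------------------------------------------------------------------

def _feature_flags(
    feature: Feature,
    contig_length: int,
    mean_role_length: float | None,
    config: ReportConfig,
) -> list[str]:
    flags = []
    if contig_length < config.short_contig_bp:
        flags.append("short contig")
    if (
        feature.start - 1 < config.edge_distance_bp
        or contig_length - feature.end < config.edge_distance_bp
    ):
        flags.append("near contig edge")
    length = feature.end - feature.start + 1
    if (
        mean_role_length is not None
        and length < config.short_feature_fraction * mean_role_length
    ):
        flags.append("short feature")
    return flags


def _mean_role_lengths(
    genomes: Sequence[AnnotatedGenome],
) -> dict[str, float]:
    totals: dict[str, list[int]] = {}
    for genome in genomes:
        for feature in genome.features:
            for role in feature.roles():
                totals.setdefault(role, []).append(feature.end - feature.start + 1)
    return {role: sum(v) / len(v) for role, v in totals.items()}


def build_problematic_roles(
    genome: AnnotatedGenome,
    annotated: Mapping[str, int],
    predicted: Mapping[str, int],
    marker_set: MarkerRoleSet | None = None,
    reference_genome: AnnotatedGenome | None = None,
    config: ReportConfig = ReportConfig(),
) -> list[ProblematicRole]:
    """One table row per scored role with predicted != annotated.

    The comment assembles, in order: the "Universal role." phrase when the
    role belongs to the marker set; the contig of each implementing
    feature with its short-contig / near-edge / short-feature flags; and,
    for roles annotated fewer times than predicted, the reference features
    implementing the role when a reference genome is available.
    """
    marker_roles = marker_set.marker_roles if marker_set is not None else set()
    contig_length = {c.contig_id: c.length for c in genome.contigs}
    corpus = [genome] + ([reference_genome] if reference_genome else [])
    mean_lengths = _mean_role_lengths(corpus)
    rows: list[ProblematicRole] = []
    for role in predicted:
        pred = int(predicted[role])
        ann = int(annotated.get(role, 0))
        if pred == ann:
            continue
        features = genome.features_for_role(role)
        parts: list[str] = []
        if role in marker_roles:
            parts.append("Universal role.")
        for feature in features:
            flags = _feature_flags(
                feature,
                contig_length[feature.contig_id],
                mean_lengths.get(role),
                config,
            )
            note = f"{feature.feature_id} on contig {feature.contig_id}"
            if flags:
                note += f" ({'; '.join(flags)})"
            parts.append(note + ".")
        if ann < pred and reference_genome is not None:
            ref_features = reference_genome.features_for_role(role)
            if ref_features:
                ids = ", ".join(f.feature_id for f in ref_features)
                parts.append(f"Reference features implementing this role: {ids}.")
        rows.append(
            ProblematicRole(
                role=role,
                predicted_count=pred,
                annotated_count=ann,
                feature_ids=[f.feature_id for f in features],
                comment=" ".join(parts),
            )
        )
    return rows


def contigs_without_reliable_roles(
    genome: AnnotatedGenome, reliable_roles: Sequence[str]
) -> list[str]:
    """Contigs carrying no feature that implements any reliable role."""
    reliable = set(reliable_roles)
    covered = {
        f.contig_id
        for f in genome.features
        if any(role in reliable for role in f.roles())
    }
    return [c.contig_id for c in genome.contigs if c.contig_id not in covered]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def find_phes_features(genome: AnnotatedGenome) -> list[Feature]:
    """Features whose function includes the pheS alpha-chain role.

    Matched by role name, tolerating an EC-number suffix on the role.
    """
    hits = []
    for feature in genome.features:
        for role in feature.roles():
            if role == PHES_ROLE or role.startswith(PHES_ROLE + " ("):
                hits.append(feature)
                break
    return hits


def classify_genome(
    completeness: float,
    contamination: float,
    fine_consistency: float,
    phes_features: Sequence[Feature],
    domain: str,
) -> tuple[bool, bool]:
    """The (good, good seed) flags.

    ``good`` applies the closed-bound criteria (contamination <= 10, fine
    consistency >= 87, completeness >= 80).  ``good seed`` requires exactly
    one pheS feature whose protein length lies in the domain's closed
    range; an unknown domain yields False with a warning.
    """
    good = (
        contamination <= GOOD_CONTAMINATION_MAX
        and fine_consistency >= GOOD_FINE_CONSISTENCY_MIN
        and completeness >= GOOD_COMPLETENESS_MIN
    )
    if domain not in PHES_LENGTH_RANGES:
        logger.warning(
            "unknown domain %r: good-seed status is indeterminate, reported False",
            domain,
        )
        return good, False
    low, high = PHES_LENGTH_RANGES[domain]
    good_seed = (
        len(phes_features) == 1
        and phes_features[0].protein_length is not None
        and low <= phes_features[0].protein_length <= high
    )
    return good, good_seed


# ---------------------------------------------------------------------------
# assembly and rendering
# ---------------------------------------------------------------------------

def build_quality_report(
    genome: AnnotatedGenome,
    consistency: ConsistencyResult,
    evalg: EvalGResult,
    marker_set: MarkerRoleSet | None = None,
    reference_genome: AnnotatedGenome | None = None,
    config: ReportConfig = ReportConfig(),
) -> QualityReport:
    """Assemble the full quality report for one scored genome."""
    good, good_seed = classify_genome(
        completeness=evalg.completeness,
        contamination=evalg.contamination,
        fine_consistency=consistency.fine_consistency,
        phes_features=find_phes_features(genome),
        domain=genome.domain,
    )
    problematic = build_problematic_roles(
        genome,
        annotated=consistency.annotated,
        predicted=consistency.predicted,
        marker_set=marker_set,
        reference_genome=reference_genome,
        config=config,
    )
    return QualityReport(
        genome_id=genome.genome_id,
        name=genome.name,
        completeness=evalg.completeness,
        contamination=evalg.contamination,
        fine_consistency=consistency.fine_consistency,
        coarse_consistency=consistency.coarse_consistency,
        good=good,
        good_seed=good_seed,
        grouping_used=evalg.grouping_used,
        problematic_roles=problematic,
        contigs_without_reliable_roles=contigs_without_reliable_roles(
            genome, list(consistency.predicted)
        ),
    )


def _tsv_row(report: QualityReport) -> list[str]:
    return [
        report.genome_id,
        report.name,
        f"{report.fine_consistency:.1f}",
        f"{report.completeness:.1f}",
        f"{report.contamination:.1f}",
        "1" if report.good else "0",
        "1" if report.good_seed else "0",
    ]


def render_batch_tsv(reports: Sequence[QualityReport]) -> str:
    """One TSV row per genome in the published quality-report column order."""
    lines = ["\t".join(TSV_COLUMNS)]
    lines.extend("\t".join(_tsv_row(r)) for r in reports)
    return "\n".join(lines) + "\n"


def _render_html(report: QualityReport, config: ReportConfig) -> str:
    def esc(x) -> str:
        return _html.escape(str(x))

    def link(feature_id: str) -> str:
        if config.url_template:
            url = config.url_template.format(feature_id=feature_id)
            return f'<a href="{esc(url)}">{esc(feature_id)}</a>'
        return esc(feature_id)

    summary_rows = "".join(
        f"<tr><th>{esc(k)}</th><td>{esc(v)}</td></tr>"
        for k, v in [
            ("Genome ID", report.genome_id),
            ("Genome Name", report.name),
            ("Fine Consistency", f"{report.fine_consistency:.1f}"),
            ("Coarse Consistency", f"{report.coarse_consistency:.1f}"),
            ("Completeness", f"{report.completeness:.1f}"),
            ("Contamination", f"{report.contamination:.1f}"),
            ("Good", report.good),
            ("Good Seed", report.good_seed),
            ("Taxonomic grouping", report.grouping_used),
        ]
    )
    problem_rows = "".join(
        "<tr>"
        f"<td>{esc(p.role)}</td>"
        f"<td>{p.predicted_count}</td>"
        f"<td>{p.annotated_count}</td>"
        f"<td>{', '.join(link(fid) for fid in p.feature_ids)}</td>"
        f"<td>{esc(p.comment)}</td>"
        "</tr>"
        for p in report.problematic_roles
    )
    flagged = (
        "<p>Contigs without reliable roles: "
        + esc(", ".join(report.contigs_without_reliable_roles))
        + "</p>"
        if report.contigs_without_reliable_roles
        else ""
    )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>Quality report for {esc(report.genome_id)}</title></head><body>"
        f"<h1>Genome quality report: {esc(report.genome_id)}</h1>"
        f"<table>{summary_rows}</table>"
        "<h2>Problematic roles</h2>"
        "<table><tr><th>Role</th><th>Predicted count</th>"
        "<th>Annotated count</th><th>Features</th><th>Comment</th></tr>"
        f"{problem_rows}</table>{flagged}</body></html>\n"
    )


def render_report(
    report: QualityReport,
    format: str,
    path: str | Path,
    config: ReportConfig = ReportConfig(),
) -> None:
    """Write the report as ``json``, ``tsv`` or ``html``.

    All three renderings carry identical score values; JSON is lossless
    (see :func:`parse_report_json`), TSV is the one-row batch layout, and
    HTML includes the five-column problematic-roles table.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        path.write_text(render_batch_tsv([report]))
    elif format == "html":
        path.write_text(_render_html(report, config))
    else:
        raise ValueError(f"unknown report format {format!r}")


def parse_report_json(path: str | Path) -> QualityReport:
    """Re-read a JSON report (inverse of ``render_report(..., 'json', ...)``)."""
    with open(path) as fh:
        doc = json.load(fh)
    return QualityReport(
        genome_id=doc["genome_id"],
        name=doc["name"],
        completeness=doc["completeness"],
        contamination=doc["contamination"],
        fine_consistency=doc["fine_consistency"],
        coarse_consistency=doc["coarse_consistency"],
        good=doc["good"],
        good_seed=doc["good_seed"],
        grouping_used=doc["grouping_used"],
        problematic_roles=[
            ProblematicRole(
                role=p["role"],
                predicted_count=p["predicted_count"],
                annotated_count=p["annotated_count"],
                feature_ids=list(p["feature_ids"]),
                comment=p["comment"],
            )
            for p in doc["problematic_roles"]
        ],
        contigs_without_reliable_roles=list(
            doc["contigs_without_reliable_roles"]
        ),
    )
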