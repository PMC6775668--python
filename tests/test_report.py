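"""Problematic-roles table, quality classification, and report rendering."""

import pytest

from geval.genome import AnnotatedGenome, Contig, Feature
from geval.markers import EvalGResult, MarkerCluster, MarkerRoleSet
from geval.report import (
    PHES_ROLE,
    ProblematicRole,
    QualityReport,
    ReportConfig,
    TSV_COLUMNS,
    build_problematic_roles,
    build_quality_report,
    classify_genome,
    contigs_without_reliable_roles,
    find_phes_features,
    parse_report_json,
    render_batch_tsv,
    render_report,
)
from geval.scoring import ConsistencyResult


def _phes(length=350):
    return Feature("g.peg.phes", "c1", 9000, 9000 + length * 3 - 1, "+",
                   PHES_ROLE, protein_length=length)


@pytest.fixture
def engineered_genome():
    """Discrepancy fixture: duplicated role, near-edge feature on a short
    contig, one short feature, and an in-range pheS copy."""
    contigs = [
        Contig("c1", 20000),
        Contig("c2", 800),     # short contig
        Contig("c3", 3000),    # carries no reliable role
    ]
    features = [
        Feature("g.peg.1", "c1", 1000, 2499, "+", "Role X"),
        Feature("g.peg.2", "c1", 3000, 4499, "+", "Role X"),  # extra copy
        Feature("g.peg.3", "c2", 3, 702, "+", "Role E"),      # near contig edge
        Feature("g.peg.4", "c1", 5000, 6499, "+", "Role S"),
        Feature("g.peg.5", "c1", 7000, 7299, "-", "Role S"),  # short feature
        _phes(),
    ]
    return AnnotatedGenome(
        genome_id="eng.1", name="Engineered fixture", domain="bacteria",
        lineage=["famE", "genE", "spE"], contigs=contigs, features=features,
    )


MARKERS = MarkerRoleSet(
    "spE", "species", [MarkerCluster(frozenset({"Role U", PHES_ROLE}))], 10
)

ANNOTATED = {"Role X": 2, "Role E": 1, "Role S": 2, "Role U": 0, PHES_ROLE: 1}
PREDICTED = {"Role X": 1, "Role E": 1, "Role S": 2, "Role U": 1, PHES_ROLE: 1}


class TestProblematicRoles:
    def test_only_engineered_discrepancies_appear_exactly_once(self, engineered_genome):
        rows = build_problematic_roles(
            engineered_genome, ANNOTATED, PREDICTED, MARKERS
        )
        assert sorted(r.role for r in rows) == ["Role U", "Role X"]

    def test_missing_universal_role_row(self, engineered_genome):
        rows = build_problematic_roles(engineered_genome, ANNOTATED, PREDICTED, MARKERS)
        row = next(r for r in rows if r.role == "Role U")
        assert row.predicted_count == 1 and row.annotated_count == 0
        assert row.feature_ids == []
        assert row.comment.startswith("Universal role.")

    def test_overrepresented_role_lists_all_features_and_contigs(
        self, engineered_genome
    ):
        rows = build_problematic_roles(engineered_genome, ANNOTATED, PREDICTED, MARKERS)
        row = next(r for r in rows if r.role == "Role X")
        assert row.feature_ids == ["g.peg.1", "g.peg.2"]
        assert "g.peg.1 on contig c1" in row.comment
        assert "g.peg.2 on contig c1" in row.comment

    def test_short_contig_and_near_edge_flags(self, engineered_genome):
        rows = build_problematic_roles(
            engineered_genome, {"Role E": 1}, {"Role E": 2}, MARKERS
        )
        comment = rows[0].comment
        assert "short contig" in comment
        assert "near contig edge" in comment

    def test_edge_flag_straddles_the_threshold(self):
        """start=5 is within 5 bp of the contig start; start=6 is not."""
        contig = Contig("c1", 100000)
        for start, flagged in [(5, True), (6, False)]:
            genome = AnnotatedGenome(
                genome_id="e", name="", domain="bacteria", lineage=["s"],
                contigs=[contig],
                features=[Feature("p", "c1", start, start + 1499, "+", "Role E")],
            )
            rows = build_problematic_roles(genome, {"Role E": 1}, {"Role E": 0})
            assert ("near contig edge" in rows[0].comment) is flagged

    def test_short_feature_flag(self, engineered_genome):
        rows = build_problematic_roles(
            engineered_genome, {"Role S": 2}, {"Role S": 1}, MARKERS
        )
        comment = rows[0].comment
        # mean Role S length is (1500+300)/2=900; 300 < 0.5*900
        assert "g.peg.5 on contig c1 (short feature)" in comment
        assert "g.peg.4 on contig c1 (" not in comment

    def test_reference_features_listed_for_missing_roles(self, engineered_genome):
        reference = AnnotatedGenome(
            genome_id="ref.1", name="", domain="bacteria", lineage=["spE"],
            contigs=[Contig("rc1", 50000)],
            features=[Feature("ref.peg.9", "rc1", 100, 1599, "+", "Role U")],
        )
        rows = build_problematic_roles(
            engineered_genome, ANNOTATED, PREDICTED, MARKERS, reference_genome=reference
        )
        row = next(r for r in rows if r.role == "Role U")
        assert "ref.peg.9" in row.comment

    def test_contigs_without_reliable_roles(self, engineered_genome):
        flagged = contigs_without_reliable_roles(
            engineered_genome, list(PREDICTED)
        )
        assert flagged == ["c3"]

    def test_row_invariants_enforced(self):
        with pytest.raises(ValueError, match="not problematic"):
            ProblematicRole("r", 1, 1, ["f"], "")
        with pytest.raises(ValueError, match="feature list"):
            ProblematicRole("r", 1, 0, ["f"], "")


class TestClassification:
    @pytest.mark.parametrize(
        "contamination,fine,comp,expected",
        [
            (10.0, 87.0, 80.0, True),   # closed bounds
            (10.01, 87.0, 80.0, False),
            (10.0, 86.99, 80.0, False),
            (10.0, 87.0, 79.99, False),
            (0.0, 100.0, 100.0, True),
        ],
    )
    def test_good_boundaries(self, contamination, fine, comp, expected):
        good, _ = classify_genome(comp, contamination, fine, [], "bacteria")
        assert good is expected

    @pytest.mark.parametrize(
        "domain,length,expected",
        [
            ("bacteria", 208, False),
            ("bacteria", 209, True),
            ("bacteria", 405, True),
            ("bacteria", 406, False),
            ("archaea", 292, False),
            ("archaea", 293, True),
            ("archaea", 652, True),
            ("archaea", 653, False),
        ],
    )
    def test_good_seed_length_boundaries(self, domain, length, expected):
        _, good_seed = classify_genome(100, 0, 100, [_phes(length)], domain)
        assert good_seed is expected

    def test_two_phes_copies_fail(self):
        _, good_seed = classify_genome(
            100, 0, 100, [_phes(), _phes()], "bacteria"
        )
        assert good_seed is False

    def test_unknown_domain_reports_false_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            _, good_seed = classify_genome(100, 0, 100, [_phes()], "eukaryota")
        assert good_seed is False
        assert "unknown domain" in caplog.text

    def test_classification_is_pure(self):
        args = (90.0, 5.0, 95.0, [_phes()], "bacteria")
        assert classify_genome(*args) == classify_genome(*args)

    def test_find_phes_tolerates_ec_suffix(self, engineered_genome):
        assert [f.feature_id for f in find_phes_features(engineered_genome)] == [
            "g.peg.phes"
        ]
        with_ec = AnnotatedGenome(
            genome_id="x", name="", domain="bacteria", lineage=["s"],
            contigs=[Contig("c", 5000)],
            features=[Feature("p", "c", 1, 1200, "+", f"{PHES_ROLE} (EC 6.1.1.20)")],
        )
        assert len(find_phes_features(with_ec)) == 1


@pytest.fixture
def full_report(engineered_genome):
    consistency = ConsistencyResult(
        fine_consistency=60.0,
        coarse_consistency=80.0,
        predicted=PREDICTED,
        annotated=ANNOTATED,
        mismatches=[("Role X", 1, 2), ("Role U", 1, 0)],
    )
    evalg = EvalGResult(
        completeness=50.0, contamination=0.0, grouping_used="spE",
        rank="species", occurring_roles={PHES_ROLE},
        counts={PHES_ROLE: 1, "Role U": 0},
    )
    return build_quality_report(
        engineered_genome, consistency, evalg, MARKERS
    )


class TestRendering:
    def test_report_assembly(self, full_report):
        assert full_report.good is False  # completeness 50 < 80
        assert full_report.good_seed is True
        assert sorted(p.role for p in full_report.problematic_roles) == [
            "Role U", "Role X",
        ]
        assert full_report.contigs_without_reliable_roles == ["c3"]

    def test_json_round_trip(self, full_report, tmp_path):
        path = tmp_path / "report.json"
        render_report(full_report, "json", path)
        assert parse_report_json(path) == full_report

    def test_tsv_layout(self, full_report, tmp_path):
        path = tmp_path / "report.tsv"
        render_report(full_report, "tsv", path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == TSV_COLUMNS
        fields = lines[1].split("\t")
        assert fields[0] == "eng.1"
        assert fields[2] == "60.0" and fields[3] == "50.0" and fields[4] == "0.0"
        assert fields[5] == "0" and fields[6] == "1"

    def test_batch_tsv_one_row_per_genome(self, full_report):
        text = render_batch_tsv([full_report, full_report])
        assert len(text.splitlines()) == 3

    def test_html_five_columns_and_no_links_by_default(self, full_report, tmp_path):
        path = tmp_path / "report.html"
        render_report(full_report, "html", path)
        html = path.read_text()
        for header in ("Role", "Predicted count", "Annotated count", "Features", "Comment"):
            assert f"<th>{header}</th>" in html
        assert "<a href" not in html
        assert "Universal role." in html

    def test_html_links_with_url_template(self, full_report, tmp_path):
        path = tmp_path / "report.html"
        config = ReportConfig(url_template="https://example.org/f/{feature_id}")
        render_report(full_report, "html", path, config=config)
        assert "https://example.org/f/g.peg.1" in path.read_text()

    def test_unknown_format_rejected(self, full_report, tmp_path):
        with pytest.raises(ValueError, match="unknown report format"):
            render_report(full_report, "xml", tmp_path / "x")
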