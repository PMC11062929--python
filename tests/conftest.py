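import pytest
from hypothesis import HealthCheck, settings

import isagap as ig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_ontology():
    return ig.paper_fixture_snomed()


@pytest.fixture(scope="session")
def chain_ontology():
    return ig.paper_fixture_chain()


@pytest.fixture()
def butterfly():
    """Two parents p, q with two shared children c, d: the smallest
    non-lattice configuration."""
    concepts = [
        ig.Concept(cid, f"{cid} node (synthetic)") for cid in ("p", "q", "c", "d")
    ] + [ig.Concept(ig.ISA_TYPE_ID, "Is a (attribute)")]
    edges = {("c", "p"), ("c", "q"), ("d", "p"), ("d", "q")}
    return ig.Ontology(concepts, edges)


@pytest.fixture()
def rf2_dir(tmp_path):
    """Write a minimal synthetic RF2 snapshot: five concepts, IS-A edges,
    one two-relation group, one ungrouped relation, one inactive row."""
    header_c = "id\teffectiveTime\tactive\tmoduleId\tdefinitionStatusId\n"
    concepts = [
        ("1001", "1", "900000000000074008"),  # Body root (primitive)
        ("1002", "1", "900000000000073002"),  # fully defined child
        ("1003", "1", "900000000000074008"),  # attribute concept
        ("1004", "1", "900000000000074008"),  # value concept
        ("1005", "1", "900000000000074008"),  # value concept
    ]
    (tmp_path / "sct2_Concept_Snapshot_TEST.txt").write_text(
        header_c + "".join(f"{i}\t20210901\t{a}\tM\t{d}\n" for i, a, d in concepts)
    )
    header_d = (
        "id\teffectiveTime\tactive\tmoduleId\tconceptId\tlanguageCode\ttypeId\tterm\tcaseSignificanceId\n"
    )
    names = {
        "1001": "Finding of trunk (finding)",
        "1002": "Swelling of trunk (finding)",
        "1003": "Some attribute (attribute)",
        "1004": "Value one (substance)",
        "1005": "Value two (substance)",
    }
    rows = "".join(
        f"d{i}\t20210901\t1\tM\t{cid}\ten\t900000000000003001\t{name}\tC\n"
        for i, (cid, name) in enumerate(names.items())
    )
    (tmp_path / "sct2_Description_Snapshot_TEST.txt").write_text(header_d + rows)
    header_r = (
        "id\teffectiveTime\tactive\tmoduleId\tsourceId\tdestinationId\trelationshipGroup\ttypeId\tcharacteristicTypeId\tmodifierId\n"
    )
    rels = [
        # active IS-A
        ("r1", "1", "1002", "1001", "0", "116680003", "900000000000011006"),
        # grouped attribute pair (relationshipGroup=1)
        ("r2", "1", "1002", "1004", "1", "1003", "900000000000011006"),
        ("r3", "1", "1002", "1005", "1", "1003", "900000000000011006"),
        # ungrouped attribute (group 0 -> singleton)
        ("r4", "1", "1001", "1004", "0", "1003", "900000000000011006"),
        # inactive row: must be ignored
        ("r5", "0", "1002", "1005", "0", "1003", "900000000000011006"),
        # stated (non-inferred) row: must be ignored
        ("r6", "1", "1002", "1004", "0", "1003", "900000000000010001"),
    ]
    (tmp_path / "sct2_Relationship_Snapshot_TEST.txt").write_text(
        header_r
        + "".join(
            f"{rid}\t20210901\t{a}\tM\t{s}\t{d}\t{g}\t{t}\t{ch}\t900000000000451002\n"
            for rid, a, s, d, g, t, ch in rels
        )
    )
    return tmp_path
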