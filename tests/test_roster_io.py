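"""Round-trip and validation behaviour of the file formats."""

import numpy as np
import pandas as pd
import pytest

from orgties import roster_io
from orgties.roster_io import (
    Nomination,
    Organization,
    Roster,
    RosterError,
    export_graph,
    read_adjacency,
    read_roster,
    read_survey,
    write_adjacency,
    write_roster,
    write_survey,
)


def test_roster_roundtrip_preserves_order_and_attributes(toy_roster, tmp_path):
    path = tmp_path / "roster.csv"
    write_roster(toy_roster, path)
    back = read_roster(path)
    assert back.ids == toy_roster.ids
    assert back.wave_membership == toy_roster.wave_membership
    for a, b in zip(back.organizations, toy_roster.organizations):
        assert a == b


def test_roster_with_all_sectors_parses(tmp_path):
    rows = ["org_id,label,sector,tasks,gatekeeper_type,waves"]
    for s in range(1, 12):
        rows.append(f"S{s:02d},Sector {s} org,{s},providing,none,w1")
    path = tmp_path / "roster.csv"
    path.write_text("\n".join(rows) + "\n")
    roster = read_roster(path)
    assert sorted({o.sector for o in roster.organizations}) == list(range(1, 12))


@pytest.mark.parametrize(
    "bad_row, match",
    [
        ("GP01,dup,5,gatekeeper,general_practitioner,w1", "GP01"),
        ("X1,bad sector,12,providing,none,w1", "sector"),
        ("X1,bad task,3,flying,none,w1", "task"),
        ("X1,inconsistent,3,gatekeeper,none,w1", "gatekeeper"),
    ],
)
def test_malformed_roster_rows_raise(tmp_path, bad_row, match):
    header = "org_id,label,sector,tasks,gatekeeper_type,waves"
    first = "GP01,doctor,5,gatekeeper,general_practitioner,w1"
    path = tmp_path / "roster.csv"
    path.write_text("\n".join([header, first, bad_row]) + "\n")
    with pytest.raises(RosterError, match=match):
        read_roster(path)


def test_survey_roundtrip(toy_roster, tmp_path):
    noms = [
        Nomination("w1", "CYF1", "s1", "MUN1", 3, frozenset({"expertise_knowledge"})),
        Nomination("w1", "MUN1", "s1", "SYC1", 2,
                   frozenset({"expertise_knowledge", "client_referral"})),
        Nomination("w1", "SYC2", "s2", "CYF1", 1, frozenset()),
    ]
    path = tmp_path / "survey.csv"
    write_survey(noms, path)
    assert read_survey(path, toy_roster) == noms


def test_survey_rejects_self_nomination_and_unknown_ids(toy_roster, tmp_path):
    path = tmp_path / "survey.csv"
    path.write_text(
        "wave,reporter,spanner,alter,frequency,exchanges\n"
        "w1,CYF1,s1,CYF1,weekly,\n"
    )
    with pytest.raises(RosterError, match="self-nomination"):
        read_survey(path, toy_roster)
    path.write_text(
        "wave,reporter,spanner,alter,frequency,exchanges\n"
        "w1,CYF1,s1,NOPE,weekly,\n"
    )
    with pytest.raises(RosterError, match="NOPE"):
        read_survey(path, toy_roster)
    path.write_text(
        "wave,reporter,spanner,alter,frequency,exchanges\n"
        "w1,CYF1,s1,MUN1,fortnightly,\n"
    )
    with pytest.raises(RosterError, match="frequency"):
        read_survey(path, toy_roster)


def test_empty_survey_yields_empty_list(toy_roster, tmp_path, caplog):
    path = tmp_path / "survey.csv"
    path.write_text("wave,reporter,spanner,alter,frequency,exchanges\n")
    with caplog.at_level("WARNING"):
        assert read_survey(path, toy_roster) == []
    assert any("no nominations" in r.message for r in caplog.records)


def test_adjacency_roundtrip_and_errors(tmp_path):
    labels = ["A", "B", "C"]
    m = pd.DataFrame(
        np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]), index=labels, columns=labels
    )
    path = tmp_path / "adj.csv"
    write_adjacency(m, path)
    assert read_adjacency(path).equals(m)

    zero = pd.DataFrame(np.zeros((3, 3), dtype=int), index=labels, columns=labels)
    write_adjacency(zero, path)
    assert read_adjacency(path).equals(zero)

    with pytest.raises(RosterError, match="label"):
        write_adjacency(
            pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["B", "A"]), path
        )
    with pytest.raises(RosterError, match="square"):
        write_adjacency(pd.DataFrame(np.zeros((2, 3))), path)


def test_graphml_export_flags_critical_edges(toy_roster, tmp_path):
    import networkx as nx

    ids = toy_roster.ids
    adj = pd.DataFrame(np.zeros((5, 5), dtype=int), index=ids, columns=ids)
    for a, b in [("CYF1", "MUN1"), ("MUN1", "EDU1"), ("CYF1", "EDU1")]:
        adj.loc[a, b] = adj.loc[b, a] = 1
    path = tmp_path / "net.graphml"
    export_graph(adj, toy_roster, [("CYF1", "MUN1")], path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 5
    assert g.nodes["CYF1"]["gatekeeper_type"] == "center_youth_family"
    critical = [e for e, d in g.edges.items() if d["is_critical"]]
    assert len(critical) == 1 and set(critical[0]) == {"CYF1", "MUN1"}


def test_graphml_export_of_empty_network(toy_roster, tmp_path):
    import networkx as nx

    ids = toy_roster.ids
    adj = pd.DataFrame(np.zeros((5, 5), dtype=int), index=ids, columns=ids)
    path = tmp_path / "empty.graphml"
    export_graph(adj, toy_roster, [], path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 5 and g.number_of_edges() == 0


def test_duplicate_roster_ids_rejected():
    org = Organization("A", "a", 3, frozenset({"providing"}))
    with pytest.raises(RosterError, match="duplicate"):
        Roster([org, org])


def test_frequency_tokens_cover_scale():
    assert roster_io.FREQ_LEVELS == {"annual": 1, "monthly": 2, "weekly": 3, "daily": 4}
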