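"""Shared fixtures: a small hand-built roster and contact networks."""

import numpy as np
import pytest

from orgties.netbuild import ContactNetwork
from orgties.roster_io import Organization, Roster
from orgties.tiestrength import StrongTieNetwork


@pytest.fixture
def toy_roster() -> Roster:
    """Five organizations, one gatekeeper, both waves."""
    orgs = [
        Organization("CYF1", "Center for youth and family", 1,
                     frozenset({"gatekeeper"}), "center_youth_family"),
        Organization("MUN1", "Municipality team", 2, frozenset({"signaling"})),
        Organization("EDU1", "Care coordinator", 4, frozenset({"signaling"})),
        Organization("SYC1", "Youth mental health", 8, frozenset({"providing"})),
        Organization("SYC2", "Child and youth care", 8, frozenset({"providing"})),
    ]
    ids = tuple(o.org_id for o in orgs)
    return Roster(orgs, {"w1": ids, "w2": ids})


def symmetric_contact(nodes, dyads):
    """Build a ContactNetwork from {(i, j): (freq, ek, cr)} index pairs."""
    n = len(nodes)
    freq = np.zeros((n, n), dtype=int)
    ek = np.zeros((n, n), dtype=int)
    cr = np.zeros((n, n), dtype=int)
    for (i, j), (f, e, c) in dyads.items():
        freq[i, j] = freq[j, i] = f
        ek[i, j] = ek[j, i] = e
        cr[i, j] = cr[j, i] = c
    return ContactNetwork(wave="w1", nodes=list(nodes), freq=freq, ek=ek, cr=cr)


def strong_from_edges(nodes, edges, wave="w1"):
    """Build a StrongTieNetwork from a list of index-pair edges."""
    n = len(nodes)
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return StrongTieNetwork(wave=wave, nodes=list(nodes), adj=adj)
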