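"""Reading, writing and validating roster-survey network data.

Whole-network studies of inter-organizational collaboration start from a
*roster*: the bounded list of organizations that constitute the network.
Each organization is surveyed through one or more *boundary spanners* —
individual respondents who report, organization by organization, whether
their organization has contact with each other roster member, how often
(on a four-point annual/monthly/weekly/daily scale), and which resources
are exchanged in that contact (expertise & knowledge sharing, client
referral).

This module owns the on-disk formats for that data:

* roster CSV          — one row per organization (id, label, sector 1–11,
                        tasks, gatekeeper category, wave membership);
* survey CSV          — one row per nomination (wave, reporter, spanner,
                        alter, frequency token, exchange tokens);
* adjacency CSV       — square labeled integer matrix;
* GraphML             — figure-ready export with sector / gatekeeper node
                        attributes and an ``is_critical`` edge attribute.

All delimited files are UTF-8 CSV with a mandatory header; multi-valued
cells (tasks, exchanges, waves) are semicolon-joined tokens. Frequencies
are stored as human-readable tokens and mapped internally to ordinals
1–4. Parsing is strict: a malformed row raises an error naming the row
rather than being silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Contact frequency scale: ordinal codes for the four survey answers.
FREQ_LEVELS: dict[str, int] = {"annual": 1, "monthly": 2, "weekly": 3, "daily": 4}
#: Inverse map, ordinal code -> token (0 = no contact, not serialized).
FREQ_TOKENS: dict[int, str] = {v: k for k, v in FREQ_LEVELS.items()}

#: Resource-exchange types named in the survey instrument.
EXCHANGE_EK = "expertise_knowledge"
EXCHANGE_CR = "client_referral"
EXCHANGE_TOKENS: tuple[str, ...] = (EXCHANGE_EK, EXCHANGE_CR)

#: Network tasks an organization can perform.
TASK_TOKENS: tuple[str, ...] = ("gatekeeper", "signaling", "providing")

#: Gatekeeper categories: organizations legally authorized to refer
#: clients to child and youth services.
GATEKEEPER_TYPES: tuple[str, ...] = (
    "center_youth_family",
    "general_practitioner",
    "child_health_care",
)

N_SECTORS = 11


class RosterError(ValueError):
    """Raised when roster or survey input violates an invariant."""


@dataclass(frozen=True)
class Organization:
    """A network member organization.

    Parameters
    ----------
    org_id
        Unique token identifying the organization within the roster.
    label
        Free-text display name.
    sector
        Sector code 1–11 (center for youth and family, municipality,
        basic social organizations, education, general practitioners,
        health and prevention, childcare and nursery, specialized youth
        care, protection & social rehabilitation, safety, volunteer
        organizations).
    tasks
        Subset of {gatekeeper, signaling, providing}.
    gatekeeper_type
        One of the three gatekeeper categories, or ``"none"``. Must be
        consistent with the ``gatekeeper`` task flag.
    """

    org_id: str
    label: str
    sector: int
    tasks: frozenset[str] = field(default_factory=frozenset)
    gatekeeper_type: str = "none"

    def __post_init__(self) -> None:
        if not self.org_id:
            raise RosterError("org_id must be a non-empty token")
        if not 1 <= self.sector <= N_SECTORS:
            raise RosterError(
                f"organization {self.org_id!r}: sector {self.sector} outside 1-{N_SECTORS}"
            )
        bad = set(self.tasks) - set(TASK_TOKENS)
        if bad:
            raise RosterError(f"organization {self.org_id!r}: unknown task token(s) {sorted(bad)}")
        if self.gatekeeper_type != "none" and self.gatekeeper_type not in GATEKEEPER_TYPES:
            raise RosterError(
                f"organization {self.org_id!r}: unknown gatekeeper_type {self.gatekeeper_type!r}"
            )
        is_gk = "gatekeeper" in self.tasks
        if is_gk != (self.gatekeeper_type != "none"):
            raise RosterError(
                f"organization {self.org_id!r}: gatekeeper task and gatekeeper_type disagree"
            )

    @property
    def is_gatekeeper(self) -> bool:
        return self.gatekeeper_type != "none"


@dataclass(frozen=True)
class Nomination:
    """One reported contact: reporter (via a spanner) names an alter.

    ``frequency`` is the ordinal contact frequency (1=annual, 2=monthly,
    3=weekly, 4=daily); ``exchanges`` is the (possibly empty) set of
    resource types exchanged in the contact.
    """

    wave: str
    reporter: str
    spanner: str
    alter: str
    frequency: int
    exchanges: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.reporter == self.alter:
            raise RosterError(
                f"self-nomination: {self.reporter!r} reports contact with itself"
            )
        if self.frequency not in (1, 2, 3, 4):
            raise RosterError(
                f"nomination {self.reporter!r}->{self.alter!r}: "
                f"frequency {self.frequency} outside 1-4"
            )
        bad = set(self.exchanges) - set(EXCHANGE_TOKENS)
        if bad:
            raise RosterError(
                f"nomination {self.reporter!r}->{self.alter!r}: "
                f"unknown exchange token(s) {sorted(bad)}"
            )


@dataclass
class Roster:
    """Ordered list of organizations plus per-wave membership.

    Node ordering everywhere downstream (adjacency matrices, panels,
    permutation tests) follows the roster order, so the roster is the
    single source of truth for matrix indexing.
    """

    organizations: list[Organization]
    wave_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for org in self.organizations:
            if org.org_id in seen:
                raise RosterError(f"duplicate org_id {org.org_id!r} in roster")
            seen.add(org.org_id)
        for wave, members in self.wave_membership.items():
            missing = set(members) - seen
            if missing:
                raise RosterError(
                    f"wave {wave!r} membership names unknown org id(s) {sorted(missing)}"
                )

    @property
    def ids(self) -> list[str]:
        return [o.org_id for o in self.organizations]

    def __len__(self) -> int:
        return len(self.organizations)

    def __contains__(self, org_id: str) -> bool:
        return any(o.org_id == org_id for o in self.organizations)

    def by_id(self, org_id: str) -> Organization:
        for o in self.organizations:
            if o.org_id == org_id:
                return o
        raise KeyError(org_id)

    def index(self) -> dict[str, int]:
        """Map org_id -> roster position."""
        return {o.org_id: i for i, o in enumerate(self.organizations)}

    def gatekeepers(self) -> list[Organization]:
        return [o for o in self.organizations if o.is_gatekeeper]

    def members(self, wave: str) -> list[str]:
        """Org ids belonging to ``wave``, in roster order.

        A roster without any membership record for ``wave`` is treated
        as a full census: every organization is a member.
        """
        if wave in self.wave_membership:
            member_set = set(self.wave_membership[wave])
            return [i for i in self.ids if i in member_set]
        return self.ids


# ---------------------------------------------------------------------------
# token (de)serialization helpers


def _join(tokens) -> str:
    return ";".join(sorted(tokens))


def _split(cell: str) -> list[str]:
    return [t for t in (cell or "").split(";") if t]


# ---------------------------------------------------------------------------
# roster CSV

_ROSTER_COLUMNS = ("org_id", "label", "sector", "tasks", "gatekeeper_type", "waves")


def read_roster(path) -> Roster:
    """Read a roster CSV (columns: org_id, label, sector, tasks,
    gatekeeper_type, waves) into a validated :class:`Roster`.

    Row order is preserved. Duplicate ids, unknown sector codes and
    malformed task tokens are hard errors naming the offending row.
    """
    orgs: list[Organization] = []
    membership: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RosterError(f"{path}: empty roster file (header required)")
        missing = set(_ROSTER_COLUMNS[:5]) - set(reader.fieldnames)
        if missing:
            raise RosterError(f"{path}: missing required column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sector = int(row["sector"])
            except (TypeError, ValueError):
                raise RosterError(
                    f"{path}:{lineno}: sector {row.get('sector')!r} is not an integer"
                ) from None
            org = Organization(
                org_id=row["org_id"].strip(),
                label=(row.get("label") or "").strip(),
                sector=sector,
                tasks=frozenset(_split(row.get("tasks", ""))),
                gatekeeper_type=(row.get("gatekeeper_type") or "none").strip() or "none",
            )
            orgs.append(org)
            for wave in _split(row.get("waves", "")):
                membership.setdefault(wave, []).append(org.org_id)
    return Roster(orgs, {w: tuple(m) for w, m in membership.items()})


def write_roster(roster: Roster, path) -> None:
    """Write a roster to CSV; inverse of :func:`read_roster`."""
    org_waves: dict[str, list[str]] = {i: [] for i in roster.ids}
    for wave in sorted(roster.wave_membership):
        for org_id in roster.wave_membership[wave]:
            org_waves[org_id].append(wave)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ROSTER_COLUMNS)
        for org in roster.organizations:
            writer.writerow(
                [
                    org.org_id,
                    org.label,
                    org.sector,
                    _join(org.tasks),
                    org.gatekeeper_type,
                    ";".join(org_waves[org.org_id]),
                ]
            )


# ---------------------------------------------------------------------------
# survey CSV

_SURVEY_COLUMNS = ("wave", "reporter", "spanner", "alter", "frequency", "exchanges")


def read_survey(path, roster: Roster) -> list[Nomination]:
    """Read a survey nomination CSV, validating ids against ``roster``.

    Each row is one nomination. Frequency is a token (annual, monthly,
    weekly, daily). Unknown org ids, out-of-scale frequencies and
    self-nominations are hard errors; an empty file yields an empty
    list with a logged warning.
    """
    known = set(roster.ids)
    noms: list[Nomination] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty survey file, no nominations read", path)
            return []
        missing = set(_SURVEY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise RosterError(f"{path}: missing required column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            reporter, alter = row["reporter"].strip(), row["alter"].strip()
            for org_id in (reporter, alter):
                if org_id not in known:
                    raise RosterError(
                        f"{path}:{lineno}: org id {org_id!r} not in roster"
                    )
            token = row["frequency"].strip()
            if token not in FREQ_LEVELS:
                raise RosterError(
                    f"{path}:{lineno}: unknown frequency token {token!r} "
                    f"(expected one of {sorted(FREQ_LEVELS)})"
                )
            noms.append(
                Nomination(
                    wave=row["wave"].strip(),
                    reporter=reporter,
                    spanner=row["spanner"].strip(),
                    alter=alter,
                    frequency=FREQ_LEVELS[token],
                    exchanges=frozenset(_split(row.get("exchanges", ""))),
                )
            )
    if not noms:
        logger.warning("%s: survey file contained no nominations", path)
    return noms


def write_survey(noms: list[Nomination], path) -> None:
    """Write nominations to CSV; inverse of :func:`read_survey`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SURVEY_COLUMNS)
        for n in noms:
            writer.writerow(
                [n.wave, n.reporter, n.spanner, n.alter, FREQ_TOKENS[n.frequency], _join(n.exchanges)]
            )


# ---------------------------------------------------------------------------
# adjacency CSV


def write_adjacency(net: pd.DataFrame, path) -> None:
    """Write a labeled square integer matrix to CSV (first column and
    header row are org ids)."""
    _check_square(net)
    net.astype(int).to_csv(path, index=True, index_label="org_id")


def read_adjacency(path) -> pd.DataFrame:
    """Read a labeled adjacency CSV; round-trips :func:`write_adjacency`."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    _check_square(df)
    return df.astype(int)


def _check_square(df: pd.DataFrame) -> None:
    if df.shape[0] != df.shape[1]:
        raise RosterError(f"adjacency matrix is not square: shape {df.shape}")
    if list(df.index) != list(df.columns):
        raise RosterError("adjacency matrix row and column labels differ")


# ---------------------------------------------------------------------------
# GraphML export


def export_graph(net: pd.DataFrame, roster: Roster, critical_edges, path) -> None:
    """Export a binary symmetric network as GraphML for figure layout.

    Nodes carry ``label``, ``sector`` and ``gatekeeper_type`` attributes
    (gatekeepers are conventionally drawn larger); edges carry a boolean
    ``is_critical`` attribute so flow-critical relations can be drawn
    with thicker lines.
    """
    _check_square(net)
    critical = {frozenset(e) for e in critical_edges}
    g = nx.Graph()
    for org_id in net.index:
        org = roster.by_id(org_id)
        g.add_node(
            org_id,
            label=org.label,
            sector=org.sector,
            gatekeeper_type=org.gatekeeper_type,
        )
    ids = list(net.index)
    values = net.to_numpy()
    for i, u in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if values[i, j]:
                v = ids[j]
                g.add_edge(u, v, is_critical=bool(frozenset((u, v)) in critical))
    nx.write_graphml(g, path)
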