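"""Synthetic roster-survey generator with known ground truth.

Raw whole-network survey data on child service systems are rarely
shareable (the rosters identify organizations), so every stage of the
pipeline is exercised on synthetic data that emulates the statistical
structure such studies report:

* 65–135 organizations spread over 11 sectors, with three gatekeeper
  categories (center for youth and family, general practitioners,
  child health care);
* a heavily right-skewed strong-degree distribution — a few hub
  organizations (typically gatekeepers) hold a large share of the
  strong relations while most organizations hold a handful;
* roughly 80–85% of organizations active (>= 1 strong tie);
* survey response rates around 52–68%, with core (gatekeeper)
  organizations responding, so that non-response is concentrated at
  the periphery and labeled reconstruction has work to do;
* two waves with substantial tie turnover, targeting a strong-tie
  Jaccard overlap in the 0.29–0.39 band.

Generative model
----------------
Organizations fall into three latent activity classes: *hubs* (the
gatekeepers), *peripheral* organizations (a ``peripheral_fraction``
share of the rest — emulating the many specialized-care providers that
sit at the network's edge), and ordinary members. Organization i
receives a latent sociability weight

    w_i = m_i * min(u_i^(-1 / attachment_exponent), weight_cap),

with u_i ~ Uniform(0, 1) and class multiplier m_i = 1 + hub_strength
for hubs, ``periphery_damp`` for peripheral organizations, 1
otherwise. The Pareto-like u^(-1/a) factor produces a heavy right
tail (truncated at ``weight_cap`` so one draw cannot dominate the
normalization). A wave-1 contact tie on dyad (i, j) is drawn
independently with probability

    p_ij = min(base_contact_prob * w_i * w_j / mean(w)^2, p_cap).

Given contact, the probability that the tie is *strong* is likewise
dyad-specific — gatekeepers' contacts are disproportionately intense,
peripheral contacts rarely are:

    s_ij = min(strong_fraction_target * phi_i * phi_j / Z, s_cap),

with phi_i = ``gatekeeper_strong_boost`` for hubs, ``periphery_damp``
for peripheral organizations, 1 otherwise, and Z the contact-weighted
mean of phi_i * phi_j, so the overall expected strong share equals
``strong_fraction_target`` by construction. A strong tie samples its
(frequency, exchange) attributes uniformly from the five strong cells
of the classification grid, a non-strong tie from the eleven non-
strong cells. Wave 2 keeps each wave-1 tie (attributes included) with
probability ``retention`` and adds a fresh tie on each vacant dyad
with probability churn * p_ij / mean(p) — new relations form around
the same sociable organizations as existing ones, so the two waves
share one structural regime (attributes of new ties are drawn with
the same dyad propensity s_ij).

Because retained ties keep their strength and churn-born ties are
strong at the dyad rate s_ij, the expected strong-tie Jaccard between
waves, conditional on the weights, is the ratio of expectations

    E[J] ~= r * sum(P*S) / (sum(P*S) + sum((1 - P)*C*S)),

with C the dyadic churn-rate matrix,

which :func:`generate_true_networks` evaluates exactly from the model
matrices and stores on the returned :class:`GroundTruth`. In the
homogeneous special case (all phi equal) this reduces to the scalar
form r * p / (p + c * (1 - p)) of :func:`expected_strong_jaccard`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .netbuild import ContactNetwork
from .roster_io import (
    EXCHANGE_CR,
    EXCHANGE_EK,
    FREQ_TOKENS,
    GATEKEEPER_TYPES,
    N_SECTORS,
    Nomination,
    Organization,
    Roster,
)
from .tiestrength import StrongTieNetwork, strong_network

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_population",
    "generate_true_networks",
    "emit_survey",
    "simulate",
    "expected_strong_jaccard",
    "STRONG_CELLS",
    "WEAK_CELLS",
]

WAVES = ("w1", "w2")

#: (freq, ek, cr) cells of the classification grid that are strong.
STRONG_CELLS: tuple[tuple[int, int, int], ...] = (
    (2, 1, 1), (3, 1, 1), (4, 1, 1),   # multiplex, monthly or more often
    (3, 1, 0), (4, 1, 0),              # expertise & knowledge, weekly+
)
#: Non-strong cells with contact, including contact with neither
#: named resource (empty exchange set).
WEAK_CELLS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1),                          # multiplex but only annual
    (1, 1, 0), (2, 1, 0),               # expertise too infrequent
    (1, 0, 1), (2, 0, 1), (3, 0, 1), (4, 0, 1),   # referral only
    (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0),   # unnamed resource
)

#: Tasks per sector (gatekeeper flag is set per organization, not here).
_SECTOR_TASKS: dict[int, frozenset[str]] = {
    1: frozenset(),
    2: frozenset({"signaling"}),
    3: frozenset({"signaling", "providing"}),
    4: frozenset({"signaling"}),
    5: frozenset(),
    6: frozenset({"signaling"}),
    7: frozenset({"signaling", "providing"}),
    8: frozenset({"providing"}),
    9: frozenset({"providing"}),
    10: frozenset({"signaling", "providing"}),
    11: frozenset({"signaling", "providing"}),
}

#: Home sector of each gatekeeper category.
_GATEKEEPER_SECTOR = {
    "center_youth_family": 1,
    "general_practitioner": 5,
    "child_health_care": 6,
}


def _default_sector_weights() -> tuple[float, ...]:
    # Non-gatekeeper organizations: specialized youth care dominates;
    # sectors 1 and 5 are gatekeeper-only (center, GPs).
    return (0.0, 0.09, 0.12, 0.14, 0.0, 0.05, 0.10, 0.30, 0.07, 0.08, 0.05)


def _default_gatekeepers() -> dict[str, int]:
    return {"center_youth_family": 1, "general_practitioner": 10, "child_health_care": 2}


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-wave roster survey.

    Defaults are calibrated to the published summary bands of municipal
    child service networks: 119 organizations, ~80–85% active, heavy
    hub-dominated degree tail, contact density giving an average of
    five to nine strong ties per organization, 58% response with
    gatekeepers always responding, and between-wave turnover implying a
    strong-tie Jaccard near 0.35.
    """

    n_orgs: int = 119
    sector_weights: tuple[float, ...] = field(default_factory=_default_sector_weights)
    n_gatekeepers: dict[str, int] = field(default_factory=_default_gatekeepers)
    hub_strength: float = 16.0
    attachment_exponent: float = 1.8
    weight_cap: float = 15.0
    peripheral_fraction: float = 0.3
    periphery_damp: float = 0.45
    gatekeeper_strong_boost: float = 4.0
    base_contact_prob: float = 0.32
    p_cap: float = 0.9
    strong_fraction_target: float = 0.35
    s_cap: float = 0.95
    retention: float = 0.5
    churn: float = 0.30
    response_rate: float = 0.58
    core_always_respond: bool = True
    spanners_per_org: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_orgs < 1:
            raise ValueError("n_orgs must be positive")
        if len(self.sector_weights) != N_SECTORS:
            raise ValueError(f"sector_weights must have {N_SECTORS} entries")
        if abs(sum(self.sector_weights) - 1.0) > 1e-9:
            raise ValueError("sector_weights must sum to 1")
        if any(w < 0 for w in self.sector_weights):
            raise ValueError("sector_weights must be non-negative")
        unknown = set(self.n_gatekeepers) - set(GATEKEEPER_TYPES)
        if unknown:
            raise ValueError(f"unknown gatekeeper categories {sorted(unknown)}")
        if sum(self.n_gatekeepers.values()) > self.n_orgs:
            raise ValueError("more gatekeepers requested than organizations")
        for name in (
            "base_contact_prob",
            "p_cap",
            "strong_fraction_target",
            "s_cap",
            "retention",
            "churn",
            "response_rate",
            "peripheral_fraction",
            "periphery_damp",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hub_strength < 0 or self.attachment_exponent <= 0:
            raise ValueError("hub_strength must be >= 0 and attachment_exponent > 0")
        if self.weight_cap < 1:
            raise ValueError("weight_cap must be >= 1")
        if self.spanners_per_org < 1:
            raise ValueError("spanners_per_org must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "sector_weights" in raw:
            raw["sector_weights"] = tuple(raw["sector_weights"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sector_weights"] = list(self.sector_weights)
        return d


@dataclass
class GroundTruth:
    """Fully observed two-wave truth, before survey non-response.

    ``expected_jaccard`` is the model-implied expected strong-tie
    Jaccard between the waves, evaluated exactly from the dyadic
    contact and strong-propensity matrices conditional on the drawn
    sociability weights.
    """

    contact: dict[str, ContactNetwork]
    strong: dict[str, StrongTieNetwork]
    realized_retention: float
    expected_jaccard: float

    def contact_density(self, wave: str = "w1") -> float:
        net = self.contact[wave]
        n = len(net)
        return float(net.contact.sum()) / (n * (n - 1)) if n > 1 else 0.0


def generate_population(config: SynthConfig) -> Roster:
    """Draw a synthetic roster: gatekeepers in their home sectors, the
    remaining organizations multinomial over ``sector_weights``. Both
    waves contain every organization. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_orgs
    ids = [f"O{k + 1:03d}" for k in range(n)]

    gk_type = ["none"] * n
    order = rng.permutation(n)
    cursor = 0
    for cat in GATEKEEPER_TYPES:
        for _ in range(config.n_gatekeepers.get(cat, 0)):
            gk_type[order[cursor]] = cat
            cursor += 1

    weights = np.asarray(config.sector_weights, dtype=float)
    orgs: list[Organization] = []
    for k in range(n):
        if gk_type[k] != "none":
            sector = _GATEKEEPER_SECTOR[gk_type[k]]
            tasks = _SECTOR_TASKS[sector] | {"gatekeeper"}
        else:
            sector = int(rng.choice(N_SECTORS, p=weights)) + 1
            tasks = _SECTOR_TASKS[sector]
        orgs.append(
            Organization(
                org_id=ids[k],
                label=f"Organization {k + 1}",
                sector=sector,
                tasks=frozenset(tasks),
                gatekeeper_type=gk_type[k],
            )
        )
    membership = {w: tuple(ids) for w in WAVES}
    return Roster(orgs, membership)


def _assign_attributes(rng: np.random.Generator, strong_prob: np.ndarray):
    """Sample (freq, ek, cr) per tie: strong cell w.p. strong_prob[k]."""
    strong_cells = np.asarray(STRONG_CELLS)
    weak_cells = np.asarray(WEAK_CELLS)
    n_ties = len(strong_prob)
    is_strong = rng.random(n_ties) < strong_prob
    out = np.empty((n_ties, 3), dtype=int)
    k_strong = int(is_strong.sum())
    out[is_strong] = strong_cells[rng.integers(0, len(strong_cells), size=k_strong)]
    out[~is_strong] = weak_cells[rng.integers(0, len(weak_cells), size=n_ties - k_strong)]
    return out


def generate_true_networks(roster: Roster, config: SynthConfig) -> GroundTruth:
    """Draw the fully observed two-wave contact networks.

    Wave 1 follows the weighted-dyad model described in the module
    docstring; wave 2 keeps each wave-1 tie (attributes included) with
    probability ``retention`` and adds fresh ties on vacant dyads with
    probability ``churn``. All matrices are symmetric with zero
    diagonal; deterministic given the seed.
    """
    config.validate()
    n = len(roster)
    hub = np.array([1.0 if o.is_gatekeeper else 0.0 for o in roster.organizations])

    rng1 = np.random.default_rng([config.seed, 1])
    u = rng1.uniform(size=n)
    pareto = np.minimum(u ** (-1.0 / config.attachment_exponent), config.weight_cap)
    peripheral = (hub == 0) & (rng1.random(n) < config.peripheral_fraction)
    mult = np.where(hub > 0, 1.0 + config.hub_strength, np.where(peripheral, config.periphery_damp, 1.0))
    w = mult * pareto
    wbar = w.mean()
    p = config.base_contact_prob * np.outer(w, w) / (wbar * wbar)
    p = np.clip(p, 0.0, config.p_cap)
    np.fill_diagonal(p, 0.0)

    # dyadic strong propensity, normalized so the contact-weighted mean
    # equals strong_fraction_target
    phi = np.where(hub > 0, config.gatekeeper_strong_boost, np.where(peripheral, config.periphery_damp, 1.0))
    phi2 = np.outer(phi, phi)
    z = float((p * phi2).sum() / p.sum()) if p.sum() > 0 else 1.0
    s = np.clip(config.strong_fraction_target * phi2 / z, 0.0, config.s_cap)
    np.fill_diagonal(s, 0.0)

    iu = np.triu_indices(n, k=1)
    contact1 = rng1.random(len(iu[0])) < p[iu]
    attrs1 = np.zeros((len(iu[0]), 3), dtype=int)
    attrs1[contact1] = _assign_attributes(rng1, s[iu][contact1])

    # dyadic churn rate: new ties form preferentially where wave-1 ties
    # were likely, keeping the two waves in one structural regime
    p_mean = float(p[iu].mean())
    c_rate = np.clip(config.churn * p / p_mean, 0.0, 1.0) if p_mean > 0 else np.zeros_like(p)

    rng2 = np.random.default_rng([config.seed, 2])
    keep = contact1 & (rng2.random(len(iu[0])) < config.retention)
    new = (~contact1) & (rng2.random(len(iu[0])) < c_rate[iu])
    attrs2 = np.zeros((len(iu[0]), 3), dtype=int)
    attrs2[keep] = attrs1[keep]
    attrs2[new] = _assign_attributes(rng2, s[iu][new])

    # model-implied expected strong-tie Jaccard, conditional on weights
    ps = float((p * s)[iu].sum())
    cs = float(((1.0 - p) * c_rate * s)[iu].sum())
    denom = ps + cs
    expected_j = config.retention * ps / denom if denom > 0 else 0.0

    def to_network(attrs: np.ndarray, wave: str) -> ContactNetwork:
        freq = np.zeros((n, n), dtype=int)
        ek = np.zeros((n, n), dtype=int)
        cr = np.zeros((n, n), dtype=int)
        freq[iu] = attrs[:, 0]
        ek[iu] = attrs[:, 1]
        cr[iu] = attrs[:, 2]
        return ContactNetwork(
            wave=wave,
            nodes=roster.ids,
            freq=freq + freq.T,
            ek=ek + ek.T,
            cr=cr + cr.T,
        )

    net1 = to_network(attrs1, "w1")
    net2 = to_network(attrs2, "w2")
    n_w1 = int(contact1.sum())
    realized_retention = float(keep.sum()) / n_w1 if n_w1 else 0.0
    return GroundTruth(
        contact={"w1": net1, "w2": net2},
        strong={"w1": strong_network(net1), "w2": strong_network(net2)},
        realized_retention=realized_retention,
        expected_jaccard=expected_j,
    )


def expected_strong_jaccard(
    retention: float, churn: float, contact_density: float
) -> float:
    """Closed-form expected strong-tie Jaccard, homogeneous case.

    With uniform contact density p and a uniform strong rate s,
    retained ties keep their attributes and new ties are strong at the
    same rate, so in expectation |S1 ∩ S2| = s·r·p·D and
    |S1 ∪ S2| = s·D·(p + c·(1 − p)) over D dyads; the s factor
    cancels:  J ≈ r·p / (p + c·(1 − p)). With heterogeneous dyad
    propensities use :attr:`GroundTruth.expected_jaccard`, the exact
    matrix version of the same ratio.
    """
    p, r, c = contact_density, retention, churn
    denom = p + c * (1.0 - p)
    return r * p / denom if denom > 0 else 0.0


def emit_survey(
    truth: GroundTruth, roster: Roster, config: SynthConfig
) -> dict[str, list[Nomination]]:
    """Simulate the survey: responding organizations report their true
    ties through their boundary spanners.

    Per wave, each organization responds with probability
    ``response_rate`` (gatekeepers always respond when
    ``core_always_respond``). A responder's alters are split across its
    1..``spanners_per_org`` spanners; each nomination carries the true
    frequency token and exchange flags. Non-responders emit nothing —
    their ties remain recoverable from partners' reports via labeled
    reconstruction, except for ties between two non-responders.
    """
    config.validate()
    surveys: dict[str, list[Nomination]] = {}
    for widx, wave in enumerate(WAVES, start=1):
        rng = np.random.default_rng([config.seed, widx, 101])
        net = truth.contact[wave]
        nodes = net.nodes
        core = np.array([roster.by_id(i).is_gatekeeper for i in nodes])
        responds = rng.random(len(nodes)) < config.response_rate
        if config.core_always_respond:
            responds |= core
        n_spanners = rng.integers(1, config.spanners_per_org + 1, size=len(nodes))
        noms: list[Nomination] = []
        for i, org_id in enumerate(nodes):
            if not responds[i]:
                continue
            alters = np.nonzero(net.freq[i])[0]
            spanner_of = rng.integers(0, n_spanners[i], size=len(alters))
            for j, sp in zip(alters, spanner_of):
                exchanges = set()
                if net.ek[i, j]:
                    exchanges.add(EXCHANGE_EK)
                if net.cr[i, j]:
                    exchanges.add(EXCHANGE_CR)
                noms.append(
                    Nomination(
                        wave=wave,
                        reporter=org_id,
                        spanner=f"{org_id}-s{int(sp) + 1}",
                        alter=nodes[int(j)],
                        frequency=int(net.freq[i, j]),
                        exchanges=frozenset(exchanges),
                    )
                )
        surveys[wave] = noms
    return surveys


def simulate(config: SynthConfig):
    """Convenience wrapper: population -> true networks -> surveys.

    Returns ``(roster, truth, surveys)``.
    """
    roster = generate_population(config)
    truth = generate_true_networks(roster, config)
    surveys = emit_survey(truth, roster, config)
    return roster, truth, surveys


# re-export for serialization convenience
def frequency_token(level: int) -> str:
    return FREQ_TOKENS[level]
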