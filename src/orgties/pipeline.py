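"""End-to-end orchestration: simulate/load -> build -> classify ->
measure -> lambda -> QAP -> stability, with a consolidated JSON report.

The report mirrors the row structure of a descriptive network table:
one section per wave (descriptive measures, lambda analysis) plus
between-wave sections (whole-network QAP, per-gatekeeper ego QAP,
stable-network counts), so results from real roster surveys can be
laid directly beside published tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import roster_io
from .lambdasets import lambda_analysis
from .netbuild import align_panel, build_contact_network
from .netmeasures import measures
from .roster_io import Roster, read_roster, read_survey
from .stability_qap import ego_qap, jaccard, qap_jaccard, stability
from .synthgen import SynthConfig, simulate
from .tiestrength import strong_network

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: either paths to real roster
    and per-wave survey CSVs, or a :class:`SynthConfig` for a synthetic
    run. Waves are analyzed in the given order; the first two waves
    feed the longitudinal (QAP / stability) stages.
    """

    roster_path: str | None = None
    survey_paths: dict[str, str] = field(default_factory=dict)
    synth: SynthConfig | None = None
    waves: tuple[str, str] = ("w1", "w2")
    n_permutations: int = 2500
    seed: int = 0
    out_dir: str | None = None
    export_graphml: bool = True

    def validate(self) -> None:
        real = self.roster_path is not None or bool(self.survey_paths)
        if real == (self.synth is not None):
            raise ValueError(
                "provide either real input paths or a synthetic config, not both"
            )
        if real and (self.roster_path is None or not self.survey_paths):
            raise ValueError("real-data runs need both a roster path and survey paths")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and return the consolidated report.

    When ``config.out_dir`` is set, stage outputs (adjacency CSVs,
    GraphML exports, report.json) are written there as well.
    """
    config.validate()
    w1, w2 = config.waves
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------
    if config.synth is not None:
        logger.info("stage=simulate seed=%s n_orgs=%d", config.synth.seed, config.synth.n_orgs)
        roster, truth, surveys = simulate(config.synth)
        noms = {w: surveys[w] for w in config.waves}
        if out:
            roster_io.write_roster(roster, out / "roster.csv")
            for w in config.waves:
                roster_io.write_survey(noms[w], out / f"survey_{w}.csv")
    else:
        logger.info(
            "stage=load roster=%s digest=%s", config.roster_path, _digest(config.roster_path)
        )
        roster = read_roster(config.roster_path)
        noms = {}
        for w in config.waves:
            path = config.survey_paths[w]
            logger.info("stage=load survey=%s digest=%s", path, _digest(path))
            noms[w] = read_survey(path, roster)

    # ---- build + align ---------------------------------------------
    nets = {w: build_contact_network(noms[w], roster, w) for w in config.waves}
    panel = align_panel(nets[w1], nets[w2])
    contact = {w1: panel.net_w1, w2: panel.net_w2}
    strong = {w: strong_network(contact[w]) for w in config.waves}
    logger.info("stage=build panel_n=%d", len(panel.nodes))

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "orgties_version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "waves": list(config.waves),
        "n_panel_orgs": len(panel.nodes),
        "measures": {},
        "lambda": {},
    }

    # ---- per-wave descriptives and lambda sets ----------------------
    for w in config.waves:
        rep = measures(strong[w], contact[w], roster)
        report["measures"][w] = rep.as_dict()
        logger.info("stage=measures wave=%s active=%d relations=%d", w, rep.n_active, rep.relation_count)
        if strong[w].adj.sum() > 0:
            lam = lambda_analysis(strong[w])
            report["lambda"][w] = lam.as_dict()
        else:
            lam = None
            report["lambda"][w] = None
            logger.warning("stage=lambda wave=%s skipped: no strong relations", w)
        if out:
            roster_io.write_adjacency(strong[w].to_frame(), out / f"strong_{w}.csv")
            if config.export_graphml:
                roster_io.export_graph(
                    strong[w].to_frame(),
                    roster,
                    lam.critical_edges if lam else [],
                    out / f"strong_{w}.graphml",
                )

    # ---- stability --------------------------------------------------
    a, b = strong[w1].adj, strong[w2].adj
    qap = qap_jaccard(a, b, config.n_permutations, seed=config.seed)
    report["qap_whole"] = qap.as_dict()
    logger.info(
        "stage=qap seed=%d jaccard=%.3f p_two=%.4f", config.seed, qap.statistic, qap.p_two_tailed
    )

    pos = {org_id: k for k, org_id in enumerate(panel.nodes)}
    gk_reports = {}
    for gk_index, org in enumerate(roster.gatekeepers()):
        if org.org_id not in pos:
            continue
        k = pos[org.org_id]
        if a[k].sum() == 0 and b[k].sum() == 0:
            gk_reports[org.org_id] = None
            continue
        res = ego_qap(a, b, k, config.n_permutations, seed=config.seed + gk_index + 1)
        gk_reports[org.org_id] = {"gatekeeper_type": org.gatekeeper_type, **res.as_dict()}
    report["qap_gatekeepers"] = gk_reports

    stab = stability(strong[w1], strong[w2], roster)
    report["stability"] = stab.as_dict()
    report["jaccard"] = jaccard(a, b) if (a.sum() or b.sum()) else None
    if out:
        roster_io.write_adjacency(stab.stable_net.to_frame(), out / "stable.csv")
        if config.export_graphml:
            roster_io.export_graph(stab.stable_net.to_frame(), roster, [], out / "stable.graphml")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("stage=report out=%s", out / "report.json")
    return report
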