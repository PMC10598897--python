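# orgties

Whole-network analysis of **strong inter-organizational relations** in
roster surveys — built for studies of child service systems and other
bounded service-delivery networks, where integrated care depends on a
small set of strong, stable relationships and on gatekeeper
organizations that hold the network together.

Given a roster of organizations and per-wave nomination tables
(reporter, boundary spanner, alter, contact frequency, resource
exchanges), `orgties`:

1. builds symmetric valued **contact networks** per wave, imputing
   non-responders by labeled reconstruction (a relation exists if at
   least one side reported it);
2. classifies each dyad as a **strong relation** from frequency,
   reciprocity and multiplexity: strong ⇔ expertise-&-knowledge
   sharing at least weekly, or expertise-&-knowledge *and* client
   referral at least monthly;
3. computes descriptive **whole-network measures** — active
   organizations and isolates, relation counts, average degree
   centrality (relations / n), degree ranges, per-gatekeeper degrees,
   and the degree sequence behind power-law scatter plots;
4. ranks relations by **pairwise edge connectivity** λ(i, j)
   (max-flow = min-cut), builds the **lambda-set hierarchy** and
   extracts the flow-critical relations;
5. tests **longitudinal stability** with the Jaccard coefficient
   J = |E₁ ∩ E₂| / |E₁ ∪ E₂| and QAP permutation tests (simultaneous
   row/column relabeling, default 2500 permutations, add-one
   p-values), for the whole network and per gatekeeper ego network,
   plus the stable network E₁ ∩ E₂;
6. ships a calibrated **synthetic roster-survey generator** with
   known ground truth — heavy-tailed hub-dominated degree
   distributions, ~80–85% active organizations, partial response with
   responding gatekeepers, and tunable between-wave tie retention —
   so every stage is testable without access to confidential rosters.

## Worked example

Run the whole pipeline on a synthetic 119-organization, two-wave
survey:

```bash
orgties run --synthetic --seed 7 --perms 2500 --out demo/
```

```
panel n=119  active w1: 83%  jaccard=0.321  qap p=0.0008  stable relations=268
```

`demo/report.json` holds the full results. For this seed, wave 1 has
99 of 119 organizations (83%) with at least one strong relation, 544
strong relations (average degree centrality 5, range 0–37, 32% of all
contact relations); the busiest gatekeepers hold 30–37 strong ties
while the median organization holds a handful — the hub-and-spoke
signature. The top lambda set sits at λ = 34 inside the densely
interlocked hub core, marking the relation O058–O089 as most
flow-critical. Between waves the strong-tie Jaccard is 0.321 against
a permutation-null mean of 0.020 (two-tailed p ≈ 0.0008, 2500
permutations): far more overlap than chance, yet two-thirds of strong
relations turned over in one wave. 76 organizations (64%) keep at
least one stable strong relation (268 stable relations in
ordered-pair counting).

The same stages run separately (`simulate`, `build`, `ties`,
`measures`, `lambda`, `qap`, `stability`; see `orgties COMMAND
--help`), reading and writing plain CSV adjacency matrices and
GraphML exports with sector / gatekeeper node attributes and an
`is_critical` edge flag for figure layout.

As a library:

```python
from orgties import SynthConfig, simulate, build_contact_network, \
    strong_network, measures, lambda_analysis, qap_jaccard

roster, truth, surveys = simulate(SynthConfig(seed=7))
net = build_contact_network(surveys["w1"], roster, "w1")
strong = strong_network(net)
print(measures(strong, net, roster).pct_active)   # 83
```

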