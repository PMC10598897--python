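# Methods

`orgties` analyzes strong inter-organizational relations in bounded
(whole-network) roster surveys, of the kind used to study municipal
child service systems: every organization on a fixed roster is asked,
through one or more boundary spanners, which other roster members it
has contact with, how often, and which resources are exchanged. This
note documents the models, conventions and numerical choices behind
each stage, and what the synthetic generator does and does not emulate.

## From nominations to a contact network

Survey reports are directed; the analysis network is undirected. A
relation between two members is coded as existing if **at least one**
of them reported it. Operationally each dyad's frequency is the
maximum over all reports in either direction from any spanner, and
the two exchange flags (expertise-&-knowledge sharing, client
referral) are OR-ed over the same reports. Non-response is handled by
*labeled reconstruction*: a non-responder's missing row is filled from
the column of reports made about it — the elementwise maximum of the
directed report matrix with its transpose. `labeled_reconstruction`
exists as a named step for auditability even though it is
mathematically subsumed by the "at least one" symmetrization.

Design choices here that the field convention does not pin down:

* **Frequency disagreements resolve to the maximum.** The existence
  rule says a relation exists if anyone reported it; taking the
  maximum frequency is the monotone completion of that rule. Mean or
  reporter-precedence rules would break the subset relation between
  "reported at level f" and "exists at level >= f".
* **Nodes always stay in roster order.** Every matrix downstream
  (classification, QAP permutation, stable intersection) indexes nodes
  identically, so panels can be intersected and compared without
  relabeling.

Longitudinal comparison requires identical actors, so two waves are
restricted to the membership intersection before any between-wave
statistic is computed.

## Strong-tie classification

Strength combines frequency (annual=1 … daily=4), reciprocity and
multiplexity: a relation is strong iff the dyad shares expertise and
knowledge at least weekly, or exchanges both expertise & knowledge and
client referrals at least monthly. Client-referral-only contact is
never strong (referral does not require active participation of both
sides), and annual contact is never strong. Exactly 5 of the 12
(frequency x nonempty exchange pattern) cells are strong; the rule is
monotone in frequency and in adding referral to an expertise tie.
Flags on a dyad with frequency 0 violate the contact-network invariant
and raise an error rather than being coerced.

## Descriptive measures

Counts follow matrix conventions: the relation count is the cell sum
of the symmetric binary adjacency (ordered pairs — each undirected tie
counts twice), and average degree centrality is relations / n with
isolates included in the denominator. Displayed percentages and
average degrees round half-up (8.507 -> 9). These conventions are
chosen because they reproduce the internal arithmetic of published
descriptive tables in this literature (e.g. 782 relations among 119
organizations displaying as average degree 7); the acceptance tests
check exactly that.

## Lambda sets and critical relations

The flow-criticality of relations is ranked by pairwise edge
connectivity λ(i, j) — the minimum number of edges whose removal
disconnects i from j, equal to the number of edge-disjoint paths. A
*lambda set* is a maximal node group whose internal connectivity
exceeds its connectivity to any outside node. Because λ satisfies
λ(i, k) >= min(λ(i, j), λ(j, k)), thresholding the λ-matrix at each
distinct value from high to low yields a nested hierarchy, and every
threshold component of size >= 2 is a lambda set. The *critical
edges* are the network edges internal to the top (highest-λ) set; if
several sets tie at the top level they are ranked by their earliest
member in roster order and the first supplies the critical edges —
the tie rule is declared, not derived, since published analyses report
single critical dyads without stating one.

Numerically, λ is computed per connected component from a Gomory–Hu
tree with unit capacities (n − 1 max-flow calls per component instead
of O(n²)); λ(i, j) is the minimum edge weight on the unique tree path.
At roster scale (~135 nodes) this completes in milliseconds. The test
suite verifies the matrix against an exhaustive minimum-cut oracle
(enumeration of all vertex bipartitions) on every connected graph with
up to 6 nodes and on bridge/barbell graphs up to 8.

## Stability: Jaccard and QAP

Between-wave overlap of the binary strong-tie networks is the Jaccard
coefficient over unordered off-diagonal dyads; it is undefined (an
error, not 0) when both waves are edgeless. Significance uses the
Quadratic Assignment Procedure: B permutations (default 2500, sampled
with replacement) relabel one matrix's nodes by a uniform random
permutation applied simultaneously to rows and columns, recomputing
the coefficient each time. P-values use the add-one convention
p = (1 + #extreme)/(B + 1); the two-tailed p is the doubled smaller
tail capped at 1. An exhaustive mode enumerates all n! permutations
for small n and anchors the sampled p-values in tests.

Two caveats worth stating. First, the two-tailed doubled p is
conservative when the permutation distribution has an atom at the
observed value (as any dyad-count statistic does); the one-tailed
upper p is the quantity that is uniform under an independent null up
to Monte-Carlo noise, and that is what the calibration test checks.
Second, the per-gatekeeper test is an *ego* variant — the Jaccard of
the organization's alter-tie vectors across waves, with a null that
permutes the entries of one vector. Published per-gatekeeper QAP
values in this literature do not document their exact procedure; the
ego-vector operationalization is an explicit choice of this package.

The *stable network* is the elementwise AND of the two waves'
matrices; its counts use the same ordered-pair convention as the
descriptive measures.

## Synthetic roster surveys

Because raw inter-organizational rosters are identifying and rarely
shareable, the generator produces data with the statistical signature
such studies report, with full ground truth:

* **Population.** Default 119 organizations over 11 sectors; 13
  gatekeepers (1 center for youth and family, 10 general
  practitioners, 2 child health care) placed in their home sectors,
  the rest multinomial over sector weights dominated by specialized
  youth care.
* **Contact model.** Each organization gets a sociability weight
  w = m * min(u^(-1/1.8), 15), u ~ U(0,1), with class multiplier
  m = 17 for gatekeeper hubs, 0.45 for a peripheral 30% of the rest,
  1 otherwise; ties are independent Bernoulli with
  p_ij ∝ w_i w_j (rate 0.32, capped at 0.9). The truncated Pareto
  factor gives the heavy right tail; the hub multiplier concentrates
  degree on gatekeepers.
* **Strength model.** Given contact, a tie is strong with dyadic
  probability s_ij ∝ phi_i phi_j (phi = 4 for hubs, 0.45 for
  periphery), normalized so the expected overall strong share is 0.35;
  strong ties draw attributes uniformly from the 5 strong grid cells,
  others from the 11 non-strong cells. Gatekeepers' contacts being
  disproportionately strong is what lets a network have both hub
  degrees of 30–60 and 15–20% isolates, which no homogeneous model
  reproduces.
* **Two waves.** Wave 2 keeps each wave-1 tie (attributes included)
  with probability 0.5 and adds new ties on vacant dyads at rate
  0.30 * p_ij / mean(p) — new relations form around the same sociable
  organizations. These defaults put the strong-tie Jaccard near 0.31
  and let the wave-2 strong count grow slightly, both matching
  published values. The model-implied expected Jaccard,
  r Σ(PS) / (Σ(PS) + Σ((1−P)CS)), is evaluated exactly per draw and
  stored on `GroundTruth.expected_jaccard`; realized overlap tracks it
  within ±0.05 over 20 seeds.
* **Survey.** Each organization responds with probability 0.58
  (gatekeepers always); responders report all their true ties, split
  across 1–2 boundary spanners. Only ties between two non-responders
  are unrecoverable, so with full response the pipeline reconstructs
  the truth exactly — the recovery tests rely on this.

Randomness is `numpy` `default_rng` seeded from (seed, stage), so a
configuration is fully reproducible and the two waves use independent
streams.

What the generator does **not** emulate: membership churn between
waves (every organization is in both waves, whereas real panels lose
and gain members), sector-assortative mixing, within-organization
disagreement between spanners (spanners partition alters but never
contradict each other), and any feedback between waves beyond tie
retention. Passing tests therefore demonstrate correctness of the
pipeline's computations and calibration of aggregate structure, not
fidelity to any particular real network's micro-structure.

## Problem sizes and test design

Oracle comparisons use sizes where exhaustive enumeration is exact:
all connected graphs on <= 6 nodes for connectivity, all n! <= 720
permutations for QAP. Calibration checks use 20 generator seeds at
n = 119; the QAP uniformity check uses 200 replicates of 2500
permutations on 40-node networks, where the dyad count (780) makes the
discrete p-value grid fine enough for a Kolmogorov–Smirnov test.
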