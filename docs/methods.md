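# Methods

## Scope and model

The package detects cross-kingdom horizontal gene transfer (HGT) between
plants and bacteria from two kinds of evidence: pairwise protein homology
(for candidate selection) and gene-tree topology (for the call itself).  The
underlying model is parsimony over tree incongruence: if a gene tree shows a
pure clade of one kingdom nested inside the other kingdom's part of the
tree, a single transfer explains the pattern more parsimoniously than
massive parallel loss in every other lineage.  More complex scenarios
(multiple transfers, hidden paralogy, long-branch artefacts) are not
modelled; trees whose candidates conflict are binned as UNCLEAR rather than
resolved.

## Homolog screen

Hits are BLAST-tabular records extended with query and subject lengths.  A
hit survives when

* percent identity ≥ `min_pident` (default 35, inclusive — "at least"),
* query and subject coverage > `min_cov` (default 0.80, strict) where
  coverage is the aligned residue span over the full protein length.

Coverage is computed from the alignment coordinates rather than the reported
alignment-length column, which counts gap positions; the rule is meant to be
about residue spans.  Multiple HSPs of the same pair are judged
independently — a pair survives if any single HSP passes; no HSP merging is
attempted because any merging policy would be an extra assumption.

Genes annotated "located in" one of {mitochondrion, chloroplast, etioplast,
amyloplast, proplastid, chromoplast} are removed (term matching
case-insensitive, relationship string exact): organelle proteomes descend
from bacterial endosymbionts, so their homology to bacteria is trivial.
Finally, kept hits with identity above `contam_pident` (default 76, strict)
are reported as possible assembly contamination; an empty flag list is the
expected outcome for clean assemblies, since genuine cross-kingdom homologs
diverge well below that bound.

## MAD rooting

Unrooted gene trees are rooted by minimal ancestor deviation.  For a
candidate root position, every leaf pair (b, c) induces an ancestor at the
point of its connecting path closest to the root; the pair's relative
deviation is r_bc = |2·d(anc, b)/d_bc − 1|, zero when the ancestor bisects
the path.  Along a branch of length L, writing d_ib for the distance from
the proximal endpoint i to leaf b, the deviation of a crossing pair is
|2(ρL + d_ib)/d_bc − 1| and the minimizer of the squared sum has the closed
form

    ρ* = Σ (d_bc − 2 d_ib) / d_bc²  /  (2L · Σ 1/d_bc²),

clamped to [0, 1]; same-side pairs contribute |d_ib − d_ic|/d_bc
independently of ρ.  The branch minimizing the RMS over all pairs wins; ties
(within 10⁻¹²) break on the lexicographically smallest leaf bipartition so
the result is deterministic.  Reported alongside: ρ (measured from the side
holding the smallest leaf label), the RMS score, and the ambiguity index
(best/second-best branch score).

Numerical behaviour: deviations are invariant to global branch-length
rescaling; an all-zero-length tree is an error; leaf pairs at zero path
distance (identical sequences) carry no midpoint information and are
skipped with a warning.  Multifurcations are allowed and every edge is a
candidate.  The output tree gets a new degree-2 root; support labels are
re-attached by leaf bipartition, and the support of the split branch is
copied to both daughter root edges (a convention — the two daughters
represent the same unrooted split).

The implementation is validated against an exhaustive oracle (every branch ×
a ρ grid of step 10⁻⁴, with independently computed path distances) and
against clock trees, where the true root branch must score exactly zero.

## Topology classifier

Support values are first normalized to the 0–100 ultrafast-bootstrap scale
(values ≤ 1 are fractions and are multiplied by 100).

**Mixed clades.**  A candidate is a minimal proper clade M containing both
eukaryote and bacterial leaves in which some children form a pure subclade
of one partner (at most `max_intruders` foreign leaves, default 0) while the
remaining children are purely the other partner.  Two vetoes encode the
animal/fungus guard: a plant-only nested subclade is rejected if M contains
any Amorphea leaf, and a candidate whose eukaryote side is Amorphea-only is
rejected outright — shared presence with animals or fungi is the signature
of vertical descent, not plant HGT.  The root is never a candidate: the two
domains being sisters is the vertical expectation and carries no nesting
information.

**Decision procedure.**  With tree-wide leaf fractions and
`majority_fraction` (default 0.5):

1. no candidate → NO_HGT;
2. nested eukaryote subclade in a mostly-bacterial tree → BACTERIA_TO_PLANTS
   when the subclade is vascular-plant/bryophyte only, else
   BACTERIA_TO_EUKARYOTES;
3. nested bacterial subclade in a mostly-eukaryotic tree →
   PLANTS_TO_BACTERIA when the context (the rest of M plus M's sisters) is
   exclusively plants, else EUKARYOTES_TO_BACTERIA;
4. fewer than `min_bacteria_genomes` (default 2) distinct bacterial genomes
   in M → UNCLEAR with a SINGLE_BACTERIUM flag (one bacterium could be
   assembly contamination);
5. key support = the support on M's stem; below `support_threshold`
   (default 80) adds LOW_BOOTSTRAP, absent adds NO_BOOTSTRAP — flags demote
   confidence but never delete a call;
6. the donor domain is read from M's closest sister clades, walking rootward
   until one super-group reaches the majority fraction;
7. PA involvement is PA/NPA/MIXED over the bacterial genomes in M;
8. a call is ancient-in-plants when ≥ `ancient_plant_fraction` (default 0.9)
   of the panel's vascular plants appear in the tree together with at least
   one bryophyte or alga leaf.

Candidates that survive to different categories → UNCLEAR; among agreeing
candidates the smallest clade wins.  "Mostly" is operationalized as leaf
fraction ≥ 0.5 and is configurable, since no quantitative definition exists
for manual inspection.  Algae are eukaryotes but not plants for direction
calling; they do count toward the ancientness annotation.  The percentage
acquired by plants is 100·B→P/(B→P + P→B), rounded half-up.

## Enrichment

Upper-tail hypergeometric per term: p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n),
computed with log-gamma terms combined by log-sum-exp; exact agreement with
integer-arithmetic summation is maintained to ≤ 10⁻¹² relative error over
every tuple with N ≤ 60.  Benjamini–Hochberg step-up q-values preserve
input order.  Terms smaller than `min_term_size` (default 5) are skipped.
The background universe is whatever annotated complement the caller
supplies — there is no hidden default — and N is always reported so results
stay interpretable.  Study genes outside the background are an error, never
silently dropped.  GO-graph propagation is left to the producer of the
annotation file.

The null calibration draws study sets uniformly from the background and
checks the fraction significant at p < 0.05.  Because the hypergeometric
tail is discrete, the design (N = 3000, K = 50, n = 50) is chosen so an
achievable p-value sits just below the nominal level (P(X ≥ 3) = 0.0494);
with a coarser design the realized rate would jump to a much smaller support
point and say nothing about calibration.

## Recency (patchiness)

For a gene's positive genomes, the narrowest rank among genus < family <
phylum < all whose single taxon contains them all is the containing rank;
prevalence is positives over that taxon's genome count and patchiness is its
complement.  A gene is flagged recent when confined to genus or family
(configurable) and either incompletely present or genus-confined — uniform
presence across a whole family looks fixed rather than recent.  This
statistic stands in for visual genomic-neighborhood inspection, for which no
computable procedure exists; synteny and integration-site analysis are out
of scope.

## Synthetic data

The generator is the study-conditions module, not a convenience fixture.
The species tree is a fixed backbone — ((archaea, bacteria), ((Amorphea,
Cryptista), (SAR, (algae, (bryophytes, vascular plants))))) — with random
ultrametric within-group topologies (recursive random splits with
geometrically shrinking node ages) and PA/NPA bacteria interleaved in one
bacterial clade, since those labels are ecological, not phylogenetic.
Default panel: 40 PA + 40 NPA bacteria, 4 archaea, 10 vascular plants,
2 bryophytes, 2 algae, 4 SAR, 4 Amorphea.

A gene tree is a topology copy with per-edge lognormal(0, σ) length noise,
per-leaf loss (never below 4 leaves), assigned integer supports, and —
when a transfer is planted — a prune-and-regraft that detaches the acceptor
clade and reattaches it inside the donor group.  The attachment height is
chosen so the graft stays ultrametric when geometry allows (the transfer
happens at a definite time); the sister-clade size at the graft point
(`graft_depth`, default 3) and the number of transferred bacteria
(`n_transferred`, default 3) are the knobs that exercise the
single-bacterium exclusion.  Supports are assigned, not computed by
resampling: the classifier only reads them, so drawn values in a
configurable range suffice, and every simulated branch corresponds to a
species-tree split or the graft region (a separate range exists for
branches matching no species split, which current edits never create).

Per-direction presets restrict the gene's taxon distribution to the
realistic carrier set: a gene bacteria donated to plants occurs in bacteria,
archaea and plants but not in the other eukaryote supergroups; a plant gene
acquired by three bacteria occurs in all eukaryotes and only those three
bacteria (their clade ages are kept young — they diversified after the
acquisition).  Without this restriction the tree-wide majority rules could
never hold, because the rest of the donor kingdom would still carry the
gene.  "Clean" presets use σ = 0.05, no loss and supports in [95, 100]; the
no-transfer panel uses the full default counts with σ = 0.1 and 5% loss.

What the simulation does *not* emulate: sequence-level evolution (trees are
edited directly, so alignment and tree-estimation error beyond the assigned
supports and branch noise are absent), rate heterogeneity across lineages,
hidden paralogy, incomplete lineage sorting, and real taxon sampling biases.
Passing round-trip tests therefore demonstrates that the decision rules
recover planted topological signatures under noise and loss — not that the
rules are robust to tree-estimation artefacts on real alignments.

## Problem sizes and determinism

The validation experiments use 200 trees per direction plus 200
transfer-free trees (76–106 leaves each), 100 single-bacterium transfers,
50 random + 50 clock trees for the rooting oracle, every hypergeometric
tuple with N ≤ 60, 1000 null replicates, and a 150-genome presence matrix;
the full acceptance run takes about half a minute on one CPU.  Every
generator is a pure function of its seed; derived seeds stay below 2³¹.

## Known limitations

* The classifier encodes a single-transfer parsimony argument; reconciliation
  models (duplication-transfer-loss) would be needed to weigh alternative
  scenarios, and dating of transfers is out of scope.
* Trees with several independent mixed clades of conflicting direction are
  UNCLEAR by design rather than partially resolved.
* The 76% contamination bound and the 35%/80% screen thresholds are
  conventions exposed as configuration, not re-derived quantities.
* MAD rooting assumes approximate rate constancy is informative; on trees
  whose grafted clade badly violates the clock the root can wander, which is
  why round-trip recovery is measured end to end (rooting included) rather
  than from the true rooted tree.
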