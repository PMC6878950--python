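# Methods

## The model

A venom repertoire is a binary vector over toxin families: family f is
present (1) or absent (0) in the venom proteome of species s, with `?` for
unscored cells. Each family evolves independently on a fixed rooted species
tree by discrete gain (recruitment, 0→1) and loss (1→0) events on branches.
The species tree for the canonical centipede analysis is the accepted
order-level topology over nine species
`((Sc,Tl),(Lf,(Ct,(Stm,(Er,(Cw,(Ss,Sm)))))))` with the standard clade names
(Pleurostigmophora, Phylactometria, Epimorpha, Scolopendromorpha,
Scolopendrinae, *Scolopendra*) attached to internal nodes; a ten-species
variant adds *S. viridis* as sister to *Cormocephalus westwoodi*.
Craterostigmomorpha is placed as sister to Epimorpha (the Phylactometria
hypothesis); the alternative Amalpighiata placement can be analyzed by
passing any other Newick species tree. The tree carries no meaningful
branch lengths, so all analyses are rate-free parsimony analyses:
model-based (ML/Bayesian) ancestral reconstruction is deliberately out of
scope.

## Small parsimony and event optimization

**Length.** The parsimony length of a character is computed by Hartigan's
majority-vote downpass, which reduces to Fitch's intersection/union rule on
binary nodes and handles the polytomies produced by consensus or
support-collapsed trees. Unknown (`?`) leaves carry the full state set,
contribute no cost, and are reported as unscored.

**MPR enumeration.** For trees with at most 20 internal nodes, all
internal-node assignments are enumerated and scored directly. This oracle
is deliberately independent of the dynamic programs it checks and is used
throughout the tests.

**ACCTRAN/DELTRAN.** The classical verbal definitions are ambiguous on
polytomies and at an ambiguous root, so the package fixes an explicit
operationalization as lexicographic MPR selection:

* both methods first minimize the number of state changes (the result is
  always an MPR — oracle-checked);
* ACCTRAN then minimizes the number of **independent origins**, counted as
  branch gains plus one origin when the root itself is present (a family
  present at the root must have been recruited on the stem lineage), and
  finally minimizes losses;
* DELTRAN orders the criteria as changes, then losses, then origins;
* residual ties are broken deterministically in preorder toward presence
  (ACCTRAN) or absence (DELTRAN), so deeper nodes take the preferred state
  first.

Counting the root's origin inside the ACCTRAN criterion matters: without it
a family present in two distant clades (e.g. both scutigeromorphs plus all
scolopendromorphs) would be pulled to a "free" presence at the root with a
compensating loss, whereas the correct reading of such a pattern — and the
one consistent with convergent recruitment of families such as SLPTX01 —
is two independent recruitments. With the origin counted, a root-state
recruitment is only chosen when it strictly reduces the number of origins
(as in the balanced-quartet case, where one stem recruitment plus two
losses beats two convergent gains on origins).

The implementation is a two-pass dynamic program over cost vectors
(changes, primary, secondary) that add componentwise and compare
lexicographically; the backtrace uses per-node suffix tables so the
deterministic tie preference never sacrifices optimality.

**Root origination reporting.** Whether a present root is *emitted* as a
recruitment event on the root branch is a separate reporting toggle
(`count_root_origin`, default on: the root cocktail originates on the
centipede stem). The toggle never affects state selection, only event
tables and totals; `convention_grid` reports summaries under all
combinations because published totals do not always state the convention.

**Overrides.** Gene-tree evidence can force a family to a single origin,
to exactly k origins, or pin named nodes to fixed states. Constrained
reconstructions minimize changes subject to the constraints (a DP over an
extra per-subtree gain dimension), then apply the same method criteria and
tie-breaks; unsatisfiable constraint sets raise with the conflict. Override
emission from gene trees is advisory — records are written to a YAML file
for review rather than applied silently, because curated per-family
adjustments should be inspectable.

## Tree search

The branch-and-bound search is exact: parsimony length is monotone under
stepwise taxon insertion, so any partial tree whose length exceeds the
current bound is pruned with all completions; the bound is initialized by a
greedy stepwise-addition tree and taxa are added in decreasing
character-conflict order (sum of pairwise disagreements). Character state
sets are bit-packed (two machine integers per node for "can be 0"/"can be
1" across all characters), making the per-tree Fitch pass a few bitwise
operations per node. Lengths are computed on unrooted trees by rooting at a
pendant taxon (Fitch length is root-invariant); topology identity and
strict consensus work on bipartition sets. An exhaustive enumerator
(≤8 taxa) serves as the oracle. Only equal character weights are
supported, and no heuristic searches (NNI/SPR/TBR) or bootstrap resampling
are provided.

## Reconciliation

Gene trees arrive rooted (by outgroup when non-centipede sequences are
flagged, else by midpoint) with leaves `<species>_<sequence id>` and
per-leaf proteome-confirmation flags. Outgroup leaves are used for rooting
only and pruned before mapping. LCA reconciliation maps each gene node to
the least common ancestor of its descendants' species; a node is a
duplication iff it maps to the same species-tree node as one of its
children, and a polytomy counts as at most one duplication however many
children share its mapping (a conservative minimum, appropriate after
support-based collapsing). No duplication-loss cost optimization over
rootings and no transfers are attempted.

Recruitment multiplicity optimizes the proteome flag on the gene tree under
the loss-minimizing (DELTRAN-style) rule, with the root pinned to unflagged
when outgroups are present: the number of gains is the minimal number of
independent recruitments of the family into venom, and loss events mark
within-clade losses of venom expression (the pattern of non-proteome
sequences nested inside a proteome-confirmed clade). The gain-minimizing
rule would collapse any two-clade pattern into one origin plus losses and
is therefore not used here.

## Simulators

`simulate_matrix` evolves families independently: root presence is
Bernoulli(root_presence_prob); on each branch an absent family gains with
probability `gain_rate` and a present family is lost with `loss_rate`.
Probabilities are per branch, not rate × length, because the canonical
species tree has no meaningful branch lengths. Families absent from every
tip are discarded and re-simulated so the emitted matrix satisfies the
every-family-present-somewhere invariant; the truth log records every
event and every node state and replays exactly to the emitted matrix.
All stochastic entry points take an explicit integer seed (numpy
`default_rng`) and are bit-reproducible.

`simulate_gene_tree` runs a birth-death process of gene lineages inside
the species tree: per branch each lineage duplicates at most once with
probability `duplication_rate`, and each resulting lineage is lost with
`gene_loss_rate`; surviving lineages split at speciations. Truth records
the species-tree placement (child end of the branch) of every duplication
both of whose copies left descendants. Total extinction triggers
re-simulation up to a retry cap.

The study-scale preset uses 93 families on the nine-species tree with
gain 0.06, loss 0.08, and root presence 0.05 per branch, chosen once so
that (i) the expected true root cocktail is small (~4–5 families), and
(ii) most families end up confined to a single order, the dominant feature
of real repertoire data (the tests assert a ≥50% single-order fraction
averaged over 20 seeds). What the simulator does **not** emulate:
correlated gain/loss between families, transcriptome/proteome detection
discrepancies, abundance levels, and within-species variation — so passing
tests demonstrate algorithmic correctness and statistical behavior at the
study's scale, not biological conclusions about real venoms.

## Numerical and formatting choices

* Bootstrap supports live on internal-node labels (the IQ-Tree
  convention); a reader flag accepts comment-style supports instead.
  Internal labels that do not parse as numbers are kept as clade names.
* `collapse_low_support` splices children of sub-threshold nodes into
  their parent (default threshold 50) and is idempotent; branch lengths of
  collapsed edges are dropped, as collapsed trees are used topologically.
  Zero-length branches are never collapsed automatically.
* Midpoint rooting requires branch lengths, preserves all pairwise leaf
  distances, and resolves ties deterministically (dendropy's rerooting).
* Matrix files are TSV/CSV (families as rows; the reader transposes when a
  species-rows orientation is detected) or NEXUS standard-datatype blocks
  with `CHARLABELS`. Greek letters in family names (β-PFTx) are aliased to
  ASCII (`beta-PFTx`) in files and restored losslessly on read.
* Unknown cells are excluded from richness/uniqueness/sharing summaries
  and widened to {0,1} in parsimony.
* Uniqueness fractions use each species' own proteome family count as the
  denominator.
* A branch is "within-order" iff every descendant leaf of its child
  belongs to one order — order stem branches count as within-order — and
  root-origination events count as stem-lineage events.
* Per-species event totals count the events on the root-to-tip path,
  excluding the root origination (changes since the last common ancestor).

## Problem sizes

The default suite and the acceptance script run at desk scale: exhaustive
MPR oracles on trees of ≤8 leaves (200+ random cases), exhaustive tree
search on ≤7 taxa, the 93-family preset on 9 taxa for the integrated
pipeline, and 40–120 simulated gene trees. The whole suite completes in a
few seconds on one CPU; branch and bound on the 9-taxon preset visits on
the order of 10^3 partial trees.

## Known limitations

* ACCTRAN/DELTRAN here are *defined* selections from the MPR set; other
  programs' undocumented tie-breaking (notably at degenerate cases in
  PAUP*) may differ per branch even when aggregate counts agree.
* Exhaustive oracles and the branch-and-bound guarantee are exact but
  exponential; the search is intended for matrices of ≲12 taxa.
* LCA reconciliation under gene loss gives a lower bound on duplication
  counts (tested property), not an estimate of the full history.
* The published-value checks require the study's supplementary matrix,
  which is not redistributed here; without it they are reported as skipped
  and the synthetic preset plus property suite stand in.
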