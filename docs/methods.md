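# Methods

`panpm` re-implements, at desk scale, a pangenomic strategy for finding
genes behind a lineage-restricted trait — here modeled on pseudomurein
(PM), the cell-wall polymer found only in Methanopyrales and
Methanobacteriales among archaea — and for testing how the discovered
gene families arose (vertical descent from the universal ancestor vs.
horizontal transfer from bacteria followed by duplication). This note
documents the models, the defaults and why they hold, the numerical
choices, and what the synthetic benchmark does and does not show.

## Study design and trait partition

All filters are driven by a three-way partition of the taxon sample:
`pos_A` (a single Methanopyrales-like lineage), `pos_B`
(Methanobacteriales-like lineages) and `neg` (trait-negative taxa).
The default design is ten taxa split 1 + 4 + 5, mirroring a comparison
of five PM-containing archaea against five non-PM euryarchaeotes.

## Candidate discovery

**Presence patterns.** An orthologous group (OG) is a candidate when it
is absent from every trait-negative taxon and present in (i) all
trait-positive taxa, (ii) the `pos_A` taxon plus at least three `pos_B`
taxa, or (iii) at least four `pos_B` taxa with no `pos_A` member. An OG
is reported once, with the first matching pattern in that order. The
"at least three/four" reading (rather than "exactly") is a deliberate
choice; the looser form never rejects a family the stricter form
accepts.

**Paralog expansions.** Widespread genes can still be trait-linked
through a trait-specific duplicate. An OG passes the paralog filter
when its mean copy number is >= 1.75 over trait-positive taxa, <= 1.25
over trait-negative taxa, and every trait-positive taxon has at least
one copy. Absent taxa count as zero copies: absence in the negatives
should lower the statistic, not void it.

**Six-frame rescue.** A candidate OG missing from some trait-positive
proteomes may reflect a pseudogene or a missed gene call rather than
true absence. For each missing taxon the genome is translated in all
six frames and locally aligned (Smith–Waterman semantics via Biopython's
`PairwiseAligner`, BLOSUM62, gap open −11 / extend −1) against a
consensus of the OG members (majority rule over a star alignment to the
longest member). A hit covering >= 50% of the consensus at >= 30%
identity adds a *rescued* record; member proteins are never modified.
These defaults tolerate one premature stop plus one frameshift (which
leaves a single clean frame over the remainder of the gene) while
rejecting random sequence by a wide margin.

**Completeness.** After rescue, only OGs covering every trait-positive
taxon (by member or rescued locus) are retained.

**Profile selection.** A seed alignment can recruit additional members:
a position-specific scoring matrix (log-odds against a uniform 1/20
background, pseudocount 1) is slid ungapped along each protein; hits
need >= 70% profile coverage and a mean per-position score >= 1 bit,
and at most 20 hits are kept per taxon. This replaces an HMM search;
for the clean synthetic families a PSSM is sufficient and dependency-free.

**Distribution classes.** With group-level homolog presence flags, a
candidate is `widespread` (bacteria and non-trait archaea), 
`bacteria_and_PM`, `archaea_only`, or `PM_only`. The rule is total over
its four-cell input space and requires trait-positive presence by
construction.

## Synteny

Gene orders come from GFF3 gene features sorted by (contig, start).
Per genome, maximal runs of candidate genes separated by at most
`max_gap = 3` non-candidate genes are collected; runs with >= 2
candidates are merged across genomes when they share >= 2 OGs
(transitive closure), and merged clusters supported by >= `min_taxa = 3`
genomes are reported. OGs that fall in different clusters depending on
the genome are flagged *mobile* and listed in both. A non-candidate OG
is *rescued* into a cluster when, in >= 80% of the genomes bearing the
cluster, one of its genes lies within `window = 3` genes of the span.
The thresholds are not dictated by any external source; they are the
smallest values that reproduce the qualitative behavior the method
targets (a conserved neighbor three genes away is captured; a gene four
genes away is not; clusters need not occur in every genome) and are all
configurable. Contigs are treated as linear; circularity is not modeled.

## Localization

Each protein carries a signal-peptide prediction (type, cleavage
probability, cleavage position) and a transmembrane (TM) segment count,
normally imported from external predictors as a table. The signal
peptide is removed before TM counting when the cleavage probability is
>= 0.1 (inclusive). Classification: Sec/Tat with 0 TM = `exported`;
otherwise 0 TM = `cytoplasmic`, 1 = `monotopic`, >1 = `polytopic`. A
Sec protein that retains TM segments is labeled by its TM count — a
membrane protein with a cleaved signal peptide is not "exported"; this
extends the published rule, which has no such row, and Tat is treated
like Sec because both are export pathways. A toy Kyte–Doolittle
predictor (window 19, mean hydropathy >= 1.6, greedy non-overlapping
scan) makes synthetic bundles classifiable without neural predictors.
The package ships a curated targeting table for the 23 candidate-cluster
OGs (`data/cluster_og_targeting.tsv`); TM counts reported there as ">1"
are encoded as 2, which classifies identically.

## Sequence preparation

* `mask_sites(min=0.3, max=0.3)`: keep columns whose unambiguous-residue
  fraction >= `max`, then drop sequences whose coverage of the kept
  columns < `min`. Because removing a sequence can push a kept column
  back below the threshold, the two steps iterate to a fixed point,
  which makes the operation genuinely idempotent; output never gains
  rows or columns.
* `splice_domain` extracts the residues of a column mask and drops gaps;
  `split_tandem` cuts two-domain fusions at half-length (first piece
  gets the extra residue) or at an explicit boundary.
* `dedup_sequences(identity=0.65, keep_all_taxa)`: greedy clustering in
  decreasing length order; identity is global-alignment matches over the
  shorter sequence. `keep_all_taxa` retains the longest member per
  additional taxon per cluster, so deduplication never erases a taxon.
* `prune_divergent(evalue<=1e-3, min_hits=1, identity in [0.01, 0.2))`:
  removes sequences that are significantly homologous to the reference
  set yet align at under 20% identity — too divergent to place reliably.
  A sequence >= 20% identical to any reference is never removed,
  regardless of e-value.
* `annotate_best_hit(evalue<=1e-20)`: label of the best-scoring
  significant reference; ties break on the lexicographically smaller
  reference id; otherwise `unannotated`.
* E-values use the Karlin–Altschul approximation with standard gapped
  BLOSUM62 parameters (lambda 0.267, K 0.041) and database size = total
  reference residues. This is adequate for thresholding and is not a
  re-derivation of BLAST statistics.

## Trees and clan support

Distances are Poisson-corrected mismatch fractions, d = −ln(1 − p),
computed over pairwise-comparable columns and capped at 10 for
saturated pairs. Neighbor joining minimizes the standard Q criterion
with a deterministic tie-break (smallest row-major index pair) and
clamps negative branch-length estimates to zero; on additive matrices
it provably recovers the generating topology, which the tests verify
against an exhaustive-oracle-free RF comparison. A *clan* is a leaf set
separable from all other leaves by removing one edge — the unrooted
analog of monophyly; rooted trees require true monophyly. Rooting on a
clan splits the separating edge at its midpoint.

Jackknife clan support resamples min(k, member size) sequences per
member (default k = 5, without replacement — the subset size is not
externally fixed, so a value large enough to span member diversity yet
small enough to vary across replicates was chosen once), extracts their
rows from the master alignment, re-masks at 0.3/0.3, and builds a tree
with a pluggable builder (default: NJ on Poisson distances; replicates
re-use the master alignment rather than re-aligning, which removes the
external-aligner dependency at desk scale — a re-aligning builder can be
injected). A query's support is the fraction of replicates in which its
sampled leaves form a clan; replicates where a query selects fewer than
two leaves are excluded from that query's denominator. Defaults are 100
replicates in tests and examples; 1,000 is configurable. The
majority-rule consensus includes bipartitions occurring in > 50% of
trees with their occurrence fraction as support; because jackknife
replicates sample disjoint leaf subsets, the pipeline reports per-query
support tables rather than a consensus of replicates (a
missing-taxa-tolerant supertree is out of scope).

## Origin scenarios

Leaves of a family tree carry member (MurC/D/E/F, Mur_alpha/beta/
gamma/delta) and domain (Bacteria/Archaea) annotations. Five mutually
exclusive topological predicates formalize the candidate histories:

* **A** — single ancestral gene, three independent duplications per
  domain: the archaea/bacteria bipartition exists, all eight members
  are clans, and the archaeal block does not attach to any single
  bacterial member.
* **B** — two ancestral paralogs: some bipartition yields two halves,
  each holding a two-member archaeal clan and a two-member bacterial
  clan.
* **C** — four ancestral genes: a perfect matching of archaeal to
  bacterial members such that all four mixed pairs are clans.
* **D** — one transfer plus three duplications: the archaeal block is a
  clan and the minimal clan strictly containing it adds leaves of
  exactly one bacterial member (covering both sister and nested
  attachment). Clans containing a fixed set are nested, so the minimal
  one is well defined.
* **E** — two transfers: {alpha, beta, gamma} ∪ MurD is a clan and
  {delta} ∪ MurC is a clan, and A does not hold.

A naive reading of A ("both domains are clans, four member clans per
side") is also satisfied by D topologies on unrooted trees — the
domain bipartition edge exists there too. Predicate A therefore
explicitly excludes the single-member attachment that defines D; with
that refinement each simulated scenario satisfies exactly its own
predicate on noise-free trees. A call is the unique holding predicate,
otherwise `unresolved`; with replicate trees a predicate holds when its
support reaches `min_support` (default 0.5). Whenever predicate A has
any support, the call carries a note that on an unrooted tree this
topology cannot be distinguished from four independent
bacteria-to-archaea transfers.

## Synthetic generator

The generator emits per-taxon proteomes (FASTA), genome contigs
(FASTA), gene coordinates (GFF3, 1-based inclusive), an orthogroup
table, a targeting table, and a truth ledger. Default conditions: 200
background families (present per taxon with probability 0.8, one copy),
12 strict trait-specific families (six all-positive, three
`pos_A`+3×`pos_B`, three 4×`pos_B`), 5 paralog-expanded families (one
extra copy per trait-positive taxon on a widespread background), two
planted clusters (5 families conserved in 4/5 trait-positive genomes;
3 families in 3/5), 3 pseudogenes, one background gene placed
immediately downstream of cluster A in every bearing genome, and one
candidate placed exactly 4 background genes away as a decoy.

Sequences are 300 residues; each taxon copy diverges from the family
root by an expected 0.1 substitutions/site (0.15 for paralog copies)
under a Poisson process with uniform replacement. Pseudogenes are the
true coding sequence with one internal stop codon and a 1-bp deletion,
both placed in the first 30% so that >= 70% of the gene survives in a
single reading frame — detectable by six-frame rescue at the 0.5
coverage threshold, by construction. Genomes are concatenated coding
sequences (one codon per amino acid, standard prokaryotic code) with
50-bp random spacers; strands are random and the GFF3 slot of a
pseudogene is preserved.

Two layout rules keep the benchmark's ground truth unambiguous at this
deliberately small contig size (~190 genes versus ~2,000 in a real
genome): candidate loci outside planted clusters are kept at least 5
background genes apart, so planted clusters are the only candidate
co-locations; and the decoy's gap-padding genes are drawn at random per
genome, since a pad family reused across genomes would be
indistinguishable from a genuinely conserved neighbor.

Scenario trees attach random bifurcating member subtrees (default 3–8
leaves per member, base branch length 0.1) according to each panel's
event history; branch lengths are perturbed by multiplicative
log-normal noise (sigma 0.25 by default in robustness tests), which
changes lengths but never topology.

**What the generator does not emulate:** indels and alignment
uncertainty (family members are generated pre-aligned), among-site rate
variation and non-uniform exchangeabilities, gene gain/loss dynamics,
operon structure, GC/codon-usage realism, contamination, and incomplete
lineage sorting. Passing tests therefore demonstrate the correctness of
the decision rules and their thresholds on data satisfying the model's
assumptions — not robustness to alignment error or model misspecification
on real genomes. Topology noise in the scenario study enters only
through branch lengths; a harsher benchmark would perturb topologies.

## Problem sizes and determinism

The shipped tests and the acceptance script use the default bundle (10
taxa, 212 families, ~1,700 proteins), 100 jackknife replicates, 200
clan-oracle trials, 100 additive NJ matrices, and 100 noisy trees per
scenario; the full pipeline example runs with 50 (tests: 10) jackknife
replicates. Every random draw flows from a single seed through
per-stage CRC32-derived sub-seeds, and the pipeline manifest records
SHA256 hashes of all outputs; two runs with the same configuration and
seed are byte-identical.

## Known limitations

* The k-mer Jaccard orthogroup clustering is a stand-in for a proper
  orthology pipeline and is reliable only at the generator's divergence
  scale (its default threshold of 0.2 separates within-family Jaccard
  ~0.3–0.45 from random ~0.002 by orders of magnitude, but real
  families at higher divergence would fragment).
* The PSSM profile scan is ungapped; an insertion in a true member can
  split or miss a hit.
* Scenario predicates assume each member was sampled; families missing
  a member fall back to `unresolved` rather than reduced predicates.
* Jackknife replicates subsample a fixed master alignment; support
  values do not propagate alignment uncertainty.
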