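# Methods

## Data model

A chromosome-painting experiment is stored as a homology table: for every
(karyotype, probe) pair, a list of signal loci (target chromosome, arm,
region qualifiers `prox`/`int`/`dist`, two-segment mark).  The packaged
fixture transcribes the published table of 24 HME whole-chromosome probes
(three composite — (9,10), (13,22), (16,17) — each derived from two
reference chromosomes) on 14 sigmodontine karyotypes, with the HME
reference implicit.

Two transcription rules matter for the accounting and are verified against
the table's own printed per-column totals, embedded as a checksum row:

* the totals count *painted segments*, so a `(ts)` (two-segment) signal
  counts twice, as does a signal spanning exactly the proximal and distal
  regions of an arm (a disjoint span);
* region qualifiers joined by "and" describe one locus, not two.

With these rules every one of the 14 column totals reproduces, and the
per-karyotype counts in the study's text (conserved-synteny probes and
multi-probe association pairs for NSP-C/D, NPA, NSP-E, NAM) all match.
Residual transcription ambiguities (one run-together row, three
segment marks in the most rearranged outgroup column) are resolved in
favor of the checksums and flagged as comments inside the fixture file.

Conserved synteny is judged per target chromosome, not per signal: a probe
whose signals all fall on one chromosome (e.g. HME 19 on NPA 24p distal +
24q) is conserved.  This is the counting that reproduces the published
"fourteen of 24" for *N. paracou*.

Karyotype descriptors carry 2n, FN (autosomal arm number), per-chromosome
morphology and CH-arm lists, but only where the source states them;
morphology of a pair never described is recorded as absent, and bi-armed
pairs known only from two-arm painted content are conventionally written
as submetacentric (downstream logic only distinguishes acrocentric vs
bi-armed, since painting cannot resolve centromere position more finely).

## Character coding

The automated coder emits three kinds of unordered, unweighted characters:
per-probe *block configurations* (number of signals; the co-painting probe
set and two-segment mark of each signal), binary *pairwise associations*
(two probes co-painting one chromosome — the currency in which chromosomal
signatures are written), and per-probe *morphology* classes where
descriptors exist.  States are numbered by first appearance over a fixed
taxon order, so permuting input taxa renumbers but never repartitions.
Configuration keys deliberately exclude morphology: it is unrecorded for
most outgroup chromosomes and would fragment otherwise identical states.

On the fixture this coding recovers monophyletic *Neacomys* and its
published inner structure ((NSP-C,NSP-D) with NSP-A, then NPA, with
NAM/NSP-B/NSP-E outside), but not the reciprocal monophyly of the
Akodontini and Oryzomyini tribes: one Oryzomyini karyotype (CLA) is pulled
toward the fused-genome outgroups by chance co-painting shared with them.
Tribe-level support in the source analysis comes from an expert-curated
56-character matrix distributed only as supplementary material; such a
matrix can be loaded directly (NEXUS or TNT `xread`) and is then the
authoritative input for reproducing exact tree statistics.

## Parsimony engine

Tree length uses Hartigan's generalization of the Fitch pass, so
multifurcating trees are scored exactly as given.  For search, characters
are packed into big-integer bitfields (one field per character) so a
full-tree pass is a handful of bitwise operations; empty fields (union
events) are counted through a shift-fold that isolates each field's low
bit.  Exact search is branch and bound over max–min-distance taxon
insertion with two admissible bounds (partial-tree length; states confined
to unplaced taxa).  Heuristic search does greedy random-addition followed
by TBR swapping, descending while any neighbor improves and then walking
the plateau of equal-score neighbors (bounded per start, default 40
plateau trees, to keep flat landscapes affordable); equally parsimonious
trees are pooled across starts and deduplicated by split sets, capped at
1000.  The bootstrap resamples characters with replacement, searches each
replicate (seeds derived from the top-level seed by counter), and lets
each replicate cast one split-vote shared fractionally across its best
trees; only nontrivial splits are tallied.

Ancestral states are summarized as MPR sets from a two-pass 0/1-cost
dynamic program (subtree costs down, outside costs up), which handles
polytomies and missing data exactly.  Branch changes present in every
most-parsimonious reconstruction are flagged unambiguous; others are
reported with the flag unset rather than resolved by ACCTRAN/DELTRAN,
because the source analysis states no optimization choice.  Signature
rendering orders a carrier chromosome's probes positionally
(p-telomere → centromere → q-telomere, using the region qualifiers),
letters the sub-blocks of probes 6, 7 and 8 from the registry, and prints
two-segment signals on both flanks — which is exactly how the published
node annotations are written (`19/14/19`, `(9,10)/7b/(9,10)`).

## Rearrangement tally

The units of comparison are the sub-block segments of a versioned registry
(fixture data).  Within the seven *Neacomys* karyotypes, segment identities
are pinned wherever co-painting context forces the match (6a with 21, 7b
inside the two-segment (9,10) signal, the 19/14/x complex, (13,22)/26,
12/(16,17), 20/(13,22)/4, 11/(16,17) in NPA, 1/12/(16,17) in NSP-B); the
remaining assignments maximize homology, i.e. minimize the rearrangement
events they imply.  Changing the registry's granularity changes counts,
which is why it ships as data, not code.

The tally reconstructs ancestral partitions on the published ingroup
topology by per-adjacency Fitch reconstruction (ties at the root resolve
to "not adjacent", children prefer the parental state) with transitive-
closure repair, then decomposes each branch's difference into elementary
events (k-way changes peel off the largest part so identical changes share
a signature), classifies a single segment excised from a multi-segment
chromosome into a surviving multi-segment chromosome as a translocation,
and counts each distinct event once across the tree.  On the fixture this
yields 17 fusion/fission events and 1 translocation.  Raw per-branch move
counts are kept alongside (20 on the fixture) for lower-bound checks
against pairwise partition distances.

Morphology-only comparisons are data-limited: the classifier finds the CH
contrasts the text supports (blocks HME 5, 11, 23 between the two
karyotypes of the same species, plus the X chromosome) and no pericentric
inversions, because per-pair morphologies for the remaining karyotypes are
carried only in the source's figures and per-event supplementary table.
The corresponding checks are therefore expected to report fewer blocks
than the published four-inversion / six-CH totals; this is a data gap,
not a procedural difference, and the tests document it rather than paper
over it.

## Simulator

`simulate_ancestor` distributes `n_blocks` conserved blocks over
`n_chromosomes` uniformly (each chromosome nonempty).  Defaults are 26
blocks on 22 chromosomes — a high-2n ancestor with a few ancestral
associations, at the scale of the hypothesized ancestral karyotype.  Events
act on whole blocks: fission (between blocks or through the centromere),
fusion, terminal-segment translocation, pericentric inversion (centromere
repositioning; morphology-only), and CH arm gain/loss (FN-only).  Per
branch, event counts are Poisson(rate × length) per type, applied in
shuffled order; an inapplicable draw (fusion with one chromosome left) is
replaced by a draw from the applicable types and noted.  The event log
replays from the ancestor to the tips bit-exactly, and tips are emitted as
a homology table + descriptors + registry, so the whole pipeline runs on
simulated data unchanged.

Default rates encode the qualitative ordering seen in the genus
(fusion/fission ≫ inversion > translocation ≈ CH): 0.5/0.5/0.15/0.05/0.05
per unit branch.  `LOW_RATES` (0.10/0.10/0.03/0.01/0.01, total 0.25)
implements the "at most one event per branch" regime: at higher totals a
quarter of branches carry two or more events and newly fused chromosomes
are frequently re-fissioned, which produces reversals that genuinely
mislead parsimony.

What the simulator does **not** emulate: blocks never split internally, so
simulated probes always show one signal per karyotype (real tables show
sub-block fissions); there is no hotspot structure, no Robertsonian bias,
and no correlation between CH and rearrangement sites.  Recovery results
on simulated data therefore validate the machinery — coding, search,
tally bookkeeping — not the realism of any rate estimate.

The recovery experiment scores, per replicate, the Robinson–Foulds
distance from the true topology to the closest tree of the complete
optimal set (exact search at ≤10 tips; when an internal branch carries no
event, every resolution of it ties, and recovery means the truth is among
the ties), plus the consensus RF, and compares the event tally with the
log.  Under `LOW_RATES`, 8 taxa, 50 replicates, the median RF is 0, and
the tally is exact on every replicate whose events touch disjoint blocks.

## Problem sizes and numerical choices

Test and verification runs use: heuristic searches with 4–8
random-addition starts on the 15-taxon fixture; exact-vs-exhaustive checks
at 7 taxa; assignment-enumeration oracles at ≤6 taxa; partition BFS
oracles at ≤6 segments; 50-replicate recovery at 8 taxa.  All randomness
flows from explicit seeds (numpy `default_rng`, per-replicate seeds derived
by counter).  Ties everywhere resolve deterministically: trees order by
canonical Newick, events by sorted part signatures, Fitch ambiguities by
parent preference with absent-at-root.
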