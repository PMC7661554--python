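# Methods

`aadeg` reimplements, as a tested library, the genome-resolved workflow by
which proteolytic amino-acid (AA) degrading populations are identified in
anaerobic enrichment communities: metagenome-assembled genome (MAG)
abundance from contig coverage, a census of the secretion/adhesion/transport
apparatus, AA catabolic pathway completeness and expression scoring against
matched single-substrate cultures, and rank-threshold taxonomic novelty
calls. This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the method description
left the design open.

## Inputs and trust boundary

The pipeline consumes tables, not reads: per-contig mean depths and
per-gene read counts per sample, 12-column tabular protein-search hits
against curated catalogs, signal-peptide calls, bin QC metrics, and
pairwise identity tables. Read QC, assembly, binning, gene calling,
alignment and signal-peptide prediction are upstream tools whose outputs
are taken as given; their internal cutoffs (e.g. what "low-quality
mappings" were removed before depth estimation) are therefore outside the
model.

## Bin quality and abundance

Bins are retained when completeness > 80% and contamination < 5%
(single-copy-marker estimates). Both cutoffs are strict inequalities
because that is how they are conventionally printed; identities exactly at
a cutoff are excluded. Genome coverage in a sample is the length-weighted
mean of contig depths,

    C_b = sum_i(d_i * L_i) / sum_i(L_i),

and relative abundance is coverage normalized over the retained genomes of
that sample, `a_b = C_b / sum_b'(C_b')`. Reads on unbinned contigs are
ignored by construction — abundance is "of the genomes", not of the
community. Contigs of a bin missing from a depth table count as depth 0
(with a warning) rather than being dropped, so fragmentary depth exports
bias abundance down instead of up.

## Homology filtering and the functional census

Hits are kept when identity > 50% and query coverage > 50% (both strict,
both configurable). Query coverage (alignment length over query length) is
used rather than subject coverage: the filter guards against fragmentary
query genes. When no query-length table is available the coverage clause
is skipped with a logged count rather than silently passing or failing
everything.

Best hits are resolved per (gene, category kind) — highest bitscore, ties
broken by higher identity then lexicographically smallest subject — so a
multi-domain gene may be simultaneously a peptidase and carry an adhesion
domain, but holds one label per kind. Peptidase catalytic types come from
the first letter of the MEROPS-style family code (M/S/C, everything else
"other"). A gene is a *secreted* enzyme when it carries both the category
assignment and a signal-peptide call; genes absent from the signal table
default to not-secreted (logged). Adhesion screening counts genes, not
domains, over Pfam accessions PF01103, PF00754, PF02494, PF02496. SusC
transporter genes are counted by label, and their substrate class
(polypeptide vs glucan cluster) is assigned from the highest-identity
labeled reference — an explicit nearest-reference simplification of
phylogenetic cluster placement, chosen because tree inference is out of
scope and the functional claim is testable through labeled references.

## Expression

RPKM = count / (gene length/1000) / (total mapped/1e6), with the
per-sample total taken over the gene catalog of the retained bins. A gene
is *highly expressed* in a bin and sample when its RPKM is strictly above
the median RPKM of all genes of that bin in that sample, zeros included;
the median is a whole-bin statistic (an expressed-only variant is a
configuration switch). Under a strict median at most half the genes can
qualify, and a constant expression vector yields none. Fold-over-median is
reported per gene; a zero median flags folds as infinite rather than
failing.

## Pathway completeness and expression

Each of the 20 proteinogenic AAs maps to one or more explicit catabolic
routes (ordered gene-symbol lists). A route is *complete* in a bin only
when every gene symbol is present; an AA is *encoded* when at least one of
its routes is complete (OR-semantics over alternatives — e.g. threonine
counts via the aldolase, the dehydrogenase or the ammonia-lyase route). A
route is *expressed* only when it is complete and every gene has RPKM
strictly above the threshold τ in the culture fed that AA. τ defaults to 0
— any nonzero RPKM counts — because no numeric cutoff is part of the
method; it is configurable and echoed in every report. Genes shared
between routes (the branched-chain ilvE/bkd genes, iorA/iorB) are scored
independently per route, which means planting one branched-chain AA route
necessarily encodes all three.

The shipped catalog is a best-effort reconstruction from literature-
standard anaerobic routes anchored on the named marker enzymes (alanine
dehydrogenase as a single-gene route, the 6-gene glycine decarboxylating
route, an 8-gene fermentative lysine route, three alternative threonine
routes). It is data (`aadeg/data/aa_catalog.yaml`), not code; any catalog
with the same schema can replace it, and results should always be read
relative to the catalog used.

## Taxonomic novelty

16S rRNA identity against the closest classified reference is compared to
rank thresholds: < 86.5% → novel family or higher; [86.5, 94.5) → novel
genus; ≥ 94.5% → within a known genus. Genome-level AAI < 60% against
cultured family representatives likewise flags a lineage outside described
families. Identities exactly at a threshold fall in the less-novel class;
the threshold framework does not fix this boundary semantics, so it is
documented and configurable rather than silently assumed. Note that these
are per-reference screens: a lineage can sit above the family threshold
against one reference and still be treated as a novel family after
tree-based synthesis, so lineage-level conclusions are left to the user.

AAI itself is computed from reciprocal best hits between two proteomes:
partner thresholds default to identity ≥ 30% and coverage ≥ 70%
(inclusive; these are common tool defaults standing in for unpublished
internal criteria, unlike the strict printed cutoffs above), and the AAI
of a pair is the mean of the two directional identities, which makes the
statistic exactly symmetric in the two genomes.

## The synthetic community

`synthetic.emulate_study_design()` fixes the study conditions all tests
run under: 20 single-AA cultures; three dominant proteolytic bins with
planted abundances 0.091, 0.026 and 0.202, peptidase complements of
172/109/100 genes (72/55/68 secreted), adhesion counts 3/6/7, SusC genes
mostly in the polypeptide cluster, 16/17/17 AAs encoded and 16/11/17
expressed; two minority fermenter bins (abundances 0.004/0.002, 13/16
encoded but only 5/2 expressed, 12/8 secreted peptidases); five background
generalists at 0.135 each; and one bin failing the contamination cutoff.
Mean per-bin sequencing depth defaults to 20x.

Noise model: per-contig read counts are Poisson with mean
`depth_b * L_i / read_length` (depth recomputed as reads x read length /
L), and per-gene counts are Poisson with mean proportional to planted
expression level x bin depth x gene length. Poisson was chosen as the
simplest model sufficient for recovery testing; there is deliberately no
overdispersion by default. With `noise=False` every value equals its
expectation, so every pipeline estimate must recover its planted value
exactly — a property the tests enforce. Gene sequences are not generated:
hit tables are synthesized directly, with planted-category identities
drawn in (60, 95)% and decoys below 50% identity or below 50% coverage,
because alignment itself is upstream of the pipeline's contract.

What the generator does *not* emulate, and what passing tests therefore do
not show about real data: misassembly and chimeric bins, annotation error
(the hit tables are consistent with the planted inventories by
construction), overdispersed or compositionally coupled counts,
between-sample abundance dynamics (planted abundances are constant across
cultures), multi-mapping reads, and genuine phylogenetic structure behind
the identity tables.

## Problem sizes and numerical choices

Default verification runs use 10 retained bins x 20 cultures at 20x mean
depth, with 5 seeds for recovery statistics and 10 seeds for guild-level
ordering properties — sizes at which the full pipeline runs in about a
second per community while every planted contrast remains well resolved.
Recovery under these conditions: abundance RMSE on the order of 1e-4
(bound accepted: < 0.02), planted pathway completeness recovered exactly,
planted expression states recovered with < 5% error for genes with
expected count ≥ 10 (Poisson leaves a ~e^-10 chance of a planted-active
gene drawing zero reads). Boundary probes are bisection sweeps to 1e-6.
Ties anywhere (best hits, nearest references) break deterministically as
documented, and identical inputs plus configuration produce byte-identical
TSV output.

## Known limitations

- The pathway catalog is reconstructed, not the original supplementary
  gene list; encoded/expressed counts are catalog-relative.
- Highly-expressed counts depend on the whole-bin RPKM distribution; under
  a noisy baseline roughly half of any gene set sits above the bin median,
  so planted "hot" gene counts are not sharply recoverable and are
  reported as computed rather than asserted.
- SusC cluster placement by nearest labeled reference cannot express the
  uncertainty a bootstrapped tree would.
- Prevalence screening (`mapped_fraction`) operates on mapping-statistic
  tables as provided; whether multi-mapped reads were counted once or per
  bin is a property of the upstream mapper.
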