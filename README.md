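# aadeg

Genome-resolved identification of proteolytic amino-acid-degrading
populations in anaerobic microbial communities.

In anaerobic digesters, protein hydrolysis and amino-acid (AA)
fermentation are often carried out not by the classical cultured AA
fermenters but by uncultured lineages that dominate short-term
single-substrate enrichments. `aadeg` is a tested, reusable implementation
of the comparative meta-omics workflow used to make that case from
metagenome-assembled genomes (MAGs) and matched metatranscriptomes:

- **Bin QC and abundance** — bins kept at completeness > 80% and
  contamination < 5%; genome coverage as the length-weighted mean of
  contig depths, `C_b = Σ d_i L_i / Σ L_i`; relative abundance
  `a_b = C_b / Σ C_b'` over the retained genomes of each sample.
- **Functional census** — protein-search hits filtered at identity > 50%
  and query coverage > 50%, resolved to one label per gene and category
  kind; per-bin counts of peptidases by MEROPS catalytic type (M/S/C),
  secreted enzymes (assignment + signal peptide), adhesion domains
  (PF01103, PF00754, PF02494, PF02496), SusC transporters with
  polypeptide-vs-glucan cluster placement, and electron-transfer markers
  (Hyd, Fdh, Rnf, quinol:fumarate and NADH:quinone oxidoreductases).
- **Expression** — RPKM per gene and sample; "highly expressed" = RPKM
  strictly above the bin's median in that sample.
- **AA pathway scoring** — an explicit 20-AA catabolic catalog; a route is
  complete only when *all* its genes are present, expressed only when
  every gene additionally has RPKM > τ (default 0) in the culture fed that
  AA; OR-semantics over alternative routes.
- **Taxonomic novelty** — 16S rank thresholds (86.5% family / 94.5%
  genus), AAI family cutoff ~60% with reciprocal-best-hit AAI.
- **Synthetic communities** — a seeded generator that emulates the whole
  study design (20 single-AA cultures, a dominant proteolytic guild vs
  minority fermenters) with planted ground truth, so the entire pipeline
  is testable without downloads.

It is aimed at microbiome researchers who have binned assemblies,
annotation/search tables and count tables in hand and want the downstream
genome-resolved scoring to be explicit, configurable and reproducible.

## Worked example

Generate the emulated enrichment community and run the analyses:

```sh
python analysis/01_simulate_community.py --seed 1
python analysis/02_abundance_and_census.py
python analysis/03_pathway_expression.py
python analysis/04_taxonomic_novelty.py
```

`02_abundance_and_census.py` prints:

```
abundance recovery over 10 bins x 20 samples: RMSE 4.58e-05
  proteo_1: estimated 9.1% (planted 9.1%)
  proteo_2: estimated 2.6% (planted 2.6%)
  proteo_3: estimated 20.2% (planted 20.2%)
census contrast (proteolytic vs fermenter guild):
  peptidase_total: [172, 109, 100] vs [30, 25]
  secreted_peptidases: [72, 55, 68] vs [12, 8]
  adhesion_genes: [3, 6, 7] vs [1, 0]
  susC_genes: [3, 5, 8] vs [0, 0]
```

i.e. the coverage→abundance chain reproduces the planted community
structure to within Poisson noise, and the three proteolytic bins carry an
order of magnitude more secreted peptidases and adhesion/transport genes
than the fermenter bins. `03_pathway_expression.py` then reports per bin
the number of AAs with complete (encoded) and actively transcribed
(expressed) degradation routes in the matching cultures:

```
  proteo_1: 16/16 [16/16]
  proteo_2: 17/11 [17/11]
  proteo_3: 17/17 [17/17]
  ferm_1: 13/5 [13/5]
  ferm_2: 16/2 [16/2]
planted pathway inventories recovered exactly
```

and `04_taxonomic_novelty.py` classifies the proteolytic bins as a novel
family-level lineage (best AAI 52.4–57.6% < 60%; 16S 85.3% → novel family,
88.1% → novel genus) with most SusC genes in the polypeptide-transport
cluster, while the fermenter bins fall within known genera.

The same machinery is scriptable from Python (`aadeg.RunConfig`,
`aadeg.run_pipeline`, `aadeg.synthetic`) or from the `aadeg` CLI
(`simulate`, `run`, `census`, `score-pathways`, `classify`).

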