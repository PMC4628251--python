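# sef — syntenic enhancer finder

`sef` identifies candidate enhancers that are **conserved within groups of
closely related species but sequence-divergent between groups**, yet sit in
orthologous introns and are therefore likely descended from a common
ancestral element. It implements the full analysis chain as a tested,
reusable library plus CLI:

1. **core_io** — FASTA/MAF/BED/GFF3/TSV/MEME-minimal readers & writers,
   a single 0-based half-open coordinate convention, and interval
   projection through pairwise alignments.
2. **synthetic_data** — a seeded simulator that evolves multi-group genomes
   on phylogenies with planted conserved elements, cross-group decoys,
   shared motifs, histone-mark peaks and reporter-assay count tables, so
   every stage is testable offline against known truth.
3. **orthology** — orthologous exon matching (with 70 %/100 bp projection
   for unannotated species) and derivation of orthologous introns bracketed
   by adjacent orthologous exons.
4. **conservation** — a two-state phylogenetic HMM (neutral vs. branch
   lengths × ρ = 0.3) with Felsenstein-pruning emissions, neutral-model
   fitting, Viterbi segmentation into conserved regions (ECRs), and
   \>90 %-overlap resolution.
5. **group_filter** — cross-group subtraction: 1 bp overlap against
   inter-reference alignments plus a seed-and-extend homology search
   (minScore 30, minIdentity 50, both strands).
6. **candidate_selection** — syntenic ECR sets (≥ 1 ECR per group in one
   orthologous intron), H3K4me1⁺/H3K4me3⁻ mark filtering, ≤ 3 ECRs per
   group, GO-term prioritization.
7. **motif_discovery** — simple-repeat masking, maximal exact matches
   (n ≥ 7, both strands), three-way intersection, Karlin–Altschul chance
   statistics (heptamer bitscore 13.9), and PFM matching by mean
   per-column Euclidean distance with a permutation E-value (E ≤ 0.1).
8. **assay_scoring** — reporter-assay positivity (≥ 15 % of surviving fish
   above empty-vector background) and cross-species expression
   consistency with tissue-synonym mapping.

`sef.pipeline` chains stages 3–6 over a simulated or real file bundle.
Small published tables (validated enhancer coordinates and expression
annotations) ship under `sef/data/` and are exposed by `sef.datasets`.

## CLI

```bash
sef simulate  --config cfg.yaml --out study/          # synthetic bundle + truth
sef io validate study/maf/group_fish.maf              # format checks
sef orthology --annot zf=zf.gff3 --annot mm=mm.gff3 \
              --orthologs orthologs.tsv --aln mm=zf_mm.maf \
              --pivot zf --out introns.tsv
sef conserve  --maf group.maf --neutral neutral.mod --rho 0.3 --out ecrs.bed
sef crossfilter --ecrs ecrs.bed --aln inter.maf --self-genome ref.fa \
              --genome other.fa --out kept.bed --removed removed.bed
sef select    --introns introns.tsv --ecrs fish:zf=kept.bed ... \
              --h3k4me1 fish=me1.bed --h3k4me3 fish=me3.bed \
              --go gene2go.tsv --out candidates.tsv
sef motifs    --zf zf.fa --mm mm.fa --hs hs.fa --pfm db.meme --out motifs.tsv
sef assay     --counts counts.tsv --background empty.tsv --out calls.tsv
```

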