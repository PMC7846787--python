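# mapanchor

Genetic-map-guided anchoring of draft contigs into chromosome-scale
pseudomolecules, driven by two evidence sources from a biparental RIL
(recombinant inbred line) population and linked reads:

1. **Linked-read scaffolding** — reads sharing a barcode come from one long
   molecule, so barcodes shared between the ends of different contigs are
   linkage evidence. A greedy clustering over the contig-end graph (heaviest
   edges first, used ends and cycles rejected) produces scaffold paths.
2. **LD-graph linkage groups** — pairs of markers on different contigs with
   r² > 0.8 link those contigs; connected components of the contig graph
   recover the linkage groups (one per chromosome). Contigs whose markers
   disagree on linkage group are screened as chimeric misassemblies and
   broken at the barcode-continuity minimum.
3. **Genetic ordering** — parental haplotypes are imputed with a 2-state
   Viterbi HMM, recombination breakpoints between neighbouring markers are
   counted, and centimorgans follow
   `cM = 100 · breakpoints / (generations_of_crossover · n_samples)`.
   Scaffolds are ordered by median marker cM and oriented by the Spearman
   correlation between physical position and cM, then emitted as AGP v2.1.
4. **Recombination landscape** — Marey profiles (cM vs bp), sliding-window
   recombination rates (1 Mbp window / 200 kbp step), pericentromere calls
   (rate below 0.5 cM/Mbp, i.e. more than 2 Mbp per cM), Kosambi distances
   and map summary statistics.

A first-class synthetic-data subpackage (`mapanchor.simulate`) generates
ground-truthed inputs: multi-chromosome inbred genomes with piecewise-linear
Marey maps (optional low-recombination plateau), F8 single-seed-descent RIL
populations (Poisson crossovers, no interference), fragmented contigs with
injected chimeras, and barcoded molecules whose reads project through the
truth placement — so every pipeline stage is testable without external data.

## Command-line interface

All commands accept `--config config.yaml` (any subset of
`mapanchor.config.PipelineConfig` fields), `--seed` and `--log-level`;
stochastic commands are deterministic given the seed.

```sh
# simulate a genome + fragmented contigs (truth recorded as JSON)
mapanchor --seed 1 simulate-genome --n-chr 11 --chr-length-mbp 5 \
    --cm-length 25 --mean-contig-kbp 450 --n-chimeras 3 --out-dir sim/

# genotype an F8 RIL population (VCF) and simulate linked reads (TSV)
mapanchor --seed 1 simulate-ril --genome sim/genome.json --truth sim/truth.json \
    --n-individuals 100 --out-vcf ril.vcf
mapanchor --seed 1 simulate-linked-reads --genome sim/genome.json \
    --truth sim/truth.json --molecule-coverage 30 --out-tsv barcodes.tsv

# individual stages
mapanchor filter --vcf ril.vcf --parents P_A,P_B --out-vcf filtered.vcf
mapanchor impute --vcf ril.vcf --parents P_A,P_B --out-tsv haplotypes.tsv
mapanchor linkage-groups --vcf ril.vcf --parents P_A,P_B \
    --lengths sim/contigs.tsv --out-tsv groups.tsv
mapanchor scaffold --barcodes barcodes.tsv --lengths sim/contigs.tsv \
    --out-tsv scaffolds.tsv

# full pipeline: AGP, genetic map, Marey profile, pericentromere BED, ...
mapanchor --seed 1 anchor --vcf ril.vcf --parents P_A,P_B \
    --barcodes barcodes.tsv --lengths sim/contigs.tsv --out-dir out/

# landscape from an existing map + AGP; evaluation against simulation truth
mapanchor marey --map out/genetic_map.tsv --agp out/pseudomolecules.agp --out-dir marey/
mapanchor evaluate --agp out/pseudomolecules.agp --truth sim/truth.json \
    --out-json evaluation.json
```

Barcoded alignments are consumed as a 4-column TSV
(barcode, contig, 0-based position, strand). A BX-tagged BAM converts with:

```sh
samtools view aln.bam | awk -v OFS='\t' \
  'match($0, /BX:Z:[^\t]+/) {print substr($0, RSTART+5, RLENGTH-5), $3, $4-1, (and($2,16))?"-":"+"}'
```

## Layout

```
src/mapanchor/
  config.py       pipeline thresholds (YAML-loadable)
  genotypes.py    genotype / haplotype matrices (A/B/H/missing coding)
  assembly.py     pseudomolecule objects (AGP-representable)
  io/             VCF, AGP v2.1, FASTA, TSV/BED tables
  simulate/       genome, RIL population, fragmentation, linked reads,
                  reference benchmark scenarios
  genetics/       variant filters, Viterbi imputation, breakpoint cM, Kosambi
  ld.py           r², contig linkage graph, chimera screens, LD decay
  scaffold.py     end-barcode graph, greedy paths, misassembly breaking
  anchoring.py    group assignment, ordering/orientation, truth evaluation
  landscape.py    Marey profiles, window rates, pericentromeres, summaries
  pipeline.py     end-to-end orchestration
  cli.py          click CLI (console script: mapanchor)
```
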