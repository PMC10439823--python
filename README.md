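# minite

Homology-based annotation of transposable elements (TEs) in genome
assemblies, using minimizers instead of alignment.

TEs make up the majority of many plant genomes, and annotating them with
classic alignment-based library search (BLAST-style scanning of a curated
TE library against the assembly) is a major bottleneck for large genomes.
`minite` treats each library TE as if it were a noisy long read and maps it
with the seed-and-chain strategy of modern long-read aligners:

1. **Index.** The genome is winnowed into a minimizer table: every k-mer
   (k = 15) is hashed with an invertible mixing function, and within each
   window of w = 20 bases the k-mer(s) with the minimum hash are stored,
   canonically over both strands.
2. **Search.** For each library TE, *all* overlapping k-mers (the query
   side is not subsampled) are looked up in the table; up to 10,000 hits
   are retained per TE.
3. **Chain.** Dynamic programming clusters hits that are colinear in query
   and subject into chains, one chain per putative TE copy. No base-level
   alignment is performed: the first and last clustered hit positions
   *are* the match boundaries.
4. **Merge and iterate.** Overlapping matches from all TEs are merged into
   single annotations with the hierarchical family label of their
   best-supported constituent. Because a curated library never covers the
   full diversity of a genome's TE families, the search is repeated
   (2 rounds by default) with the library augmented by the genomic
   sequences just annotated, which raises sensitivity. Final annotations
   shorter than 200 bp are discarded as likely noise.

The package also provides genome masking (soft = lowercase, hard = 'N')
from an annotation table, a base-pair-overlap comparator for two annotation
sets (directional fractions = bp precision and sensitivity, plus their
harmonic-mean F-score and length histograms), and a seeded simulator that
generates repeat genomes carrying mutated, truncated and nested TE copies
with ground-truth annotations.

Intended users: genome-assembly and TE-biology groups who need a fast
first-pass repeat annotation and mask, and method developers who need a
controlled synthetic benchmark.

## Worked example

Simulate a small repeat genome, annotate it, compare against the ground
truth and mask it:

```sh
minite simulate -o demo --seed 11 --n-families 2 --n-copies-per-family 4 \
    --te-length-min 1500 --te-length-max 2500 --substitution-rate 0.08 \
    --genome-length 80000
minite annotate -i demo/genome.fa -d demo/library.fa -o demo/te_annotations.tsv
minite compare demo/te_annotations.tsv demo/truth.tsv
minite mask -i demo/genome.fa -a demo/te_annotations.tsv -m soft \
    -o demo/genome.softmasked.fa
```

The annotation step logs per-round progress and finishes with

```
INFO final: 9 annotations, 15941 bp (min length 200 bp)
```

`demo/te_annotations.tsv` is a headerless 4-column table — sequence name,
first and last position (1-based inclusive) and family:

```
chr1	13608	15395	LTR/Gypsy/Fam0
chr1	15625	17727	LTR/Copia/Fam1
chr1	21308	23080	LTR/Gypsy/Fam0
chr1	33954	34450	LTR/Gypsy/Fam0
```

and the comparison report reads

```
bp_a	15941
bp_b	16403
bp_intersection	15941
frac_a_in_b	1.000000
frac_b_in_a	0.971834
f_score	0.985716
```

i.e. every annotated base pair lies inside a true TE copy (bp precision
1.0) and 97.2% of the truly repetitive base pairs were recovered (bp
sensitivity 0.972). The simulation planted 8 copies but 9 annotations are
reported because one copy was a nested insertion, which splits its host
copy's homology into flanking segments. The same operations are available
from Python (`minite.annotate`, `minite.mask_genome`,
`minite.compare_region_sets`, `minite.simulate`).

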