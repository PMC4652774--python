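# fmseek

Nucleotide database search built on an FMD-index: the database and its
reverse complement are indexed once (BWT, cumulative counts, checkpointed
occurrence array, rank-sampled suffix array, plus a 4^k-entry table of
k-mer bi-intervals), then queries are scanned in strides of `w - k + 1` to
find every w-length exact seed on both strands via backward/forward
bi-interval extension. Seeds are sorted by diagonal, pruned by a
diagonal-offset filter, extended to ungapped alignments with two-sided
X-drop, refined by a banded affine-gap X-drop DP, and reported with
Karlin–Altschul E-values in BLAST tabular format 6/7.

## CLI

Build the index bundle (index + lookup table, single deterministic file):

```bash
fmseek index database.fa --k 11 --r 8 --seed 0          # -> database.fa.fmseek
```

Search queries against it:

```bash
fmseek align -db database.fa.fmseek -query queries.fa \
    -outfmt 7 -num_threads 4 -word_size 28 -evalue 10
```

Output is the standard 12-column BLAST tabular layout (format 7 adds
per-query comment headers); minus-strand hits have `sstart > send`.
Soft-masking is taken from lowercase runs in the input FASTA (`-dust yes`
is accepted for compatibility but only logs a warning). Options can also
be supplied via `-config options.yaml`. Output bytes are identical for
any `-num_threads` value: the loaded index is shared read-only by all
workers and results are merged in input query order.

## Library

```python
from fmseek import (build_text, build_index, build_lookup,
                    SeedingParams, find_seed_intervals, resolve_seeds,
                    ScoringParams, extend_seeds)

text  = build_text([("chr1", "ACGT...")], rng_seed=0)
index = build_index(text, r=8)
table = build_lookup(index, k=11)
```

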