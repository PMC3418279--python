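# motifindexer

Word-counting *de novo* discovery of degenerate DNA regulatory motifs in
promoter sequence sets, for regulatory genomicists working with co-expressed
gene clusters (e.g. stress-responsive modules in plant genomes).

Transcription-factor binding sites are short (5–15 bp) and degenerate, so
`motifindexer` represents motifs as words over an 11-letter alphabet —
A, C, G, T plus the two-fold wobbles r={A,G}, y={C,T}, s={C,G}, w={A,T},
m={A,C}, k={G,T} and the wildcard n — and *exhaustively* catalogs all
11⁸ = 214,358,881 degenerate 8-mers (or all 5¹² = 244,140,625 12-mers over
A, C, G, T, n). Exhaustive word counting guarantees globally optimal hits,
unlike local-search PWM optimizers. Each word maps to an integer by reading
its letters as base-11 (or base-5) digits, indexing a dense counter array.

## The statistics

For a cluster of M co-expressed gene promoters inside a genome-wide set of
K promoters, an oligo present in m cluster promoters and k genome promoters
is scored (when k < K/2 and m > kM/K) by the hypergeometric upper tail

    pValue = P(X ≥ m),  X ~ Hypergeom(K, k, M),

computed in log space (tails of interest reach 10⁻⁴⁰). Position bias toward
the transcription start site is scored against a discrete-uniform placement
null: with S = W − L + 1 valid starts in W-bp windows (S = 993 for 8-mers in
1000-bp promoters, mean μ = 497), an oligo with n occurrence instances at
mean position p̄ gets

    z = (p̄ − μ) / sqrt((S² − 1) / (12 n)),

positive when occurrences crowd toward the TSS. Oligos qualify as potential
motifs when pValue < 10⁻⁷, or when 10⁻⁷ ≤ pValue ≤ 10⁻⁵ and z > 3. Because
significant lists are dominated by degenerate variants of a few motifs, an
iterative position-overlap filter extracts non-redundant **major motifs**:
each selected major claims its occurrence positions, any oligo sharing ≥ 10%
of its own positions with claimed ones is removed, and iteration stops when
fewer than 10 oligos remain. Reverse-complement pairs are deduplicated
(single-strand scanning makes them redundant), and q-values are
Benjamini–Hochberg over the tested family.

Two-genome extensions: (i) **conserved p-values** — run the analysis on
orthologous promoter sets in two related species and assign each oligo the
*larger* of its two p-values, which removes ~99% of random noise and lets
the cutoff relax to 10⁻⁵; (ii) a **genome-wide position-bias scan** of
restricted-degeneracy 8-mers (≤ 2 wobbles from r, y, s, w, n), intersected
across genomes.

## Worked example

Plant a degenerate 5-mer `rGTCw` near the TSS in 70% of a 25-gene cluster
within a synthetic 80-promoter genome, then recover it:

```python
import motifindexer as mi

spec = mi.FixtureSpec(
    n_genome_promoters=80, window_length=60, cluster_size=25, seed=3,
    plants=(mi.PlantedMotif("rGTCw", cluster_fraction=0.7, genome_fraction=0.02,
                            positions=("tss_biased", 40, 56, 1.0)),),
)
genome, cluster_ids, truth = mi.generate_fixture(spec)
genome_index = mi.index_promoters(genome, mi.ALPHA11, word_length=5)
cluster = mi.subset_by_ids(genome, cluster_ids)
result = mi.analyze_cluster(cluster, genome_index,
                            p_strict=1e-6, p_relaxed=1e-4, stop_below=0)
print(result.candidates.head(5).drop(columns="code").to_string(index=False))
print("major motifs:", result.majors.words)
```

prints

```
motif  m  k   pvalue   qvalue     fold  n  mean_position        z
rGTCw 20 32 0.000001 0.023552 2.000000 23       44.73913 4.818352
rGTCn 21 36 0.000002 0.023552 1.866667 25       44.88000 5.067057
nrGTC 21 36 0.000002 0.023552 1.866667 25       43.88000 4.757712
rGyCw 21 39 0.000019 0.150575 1.723077 24       45.00000 5.001053
rGkCw 20 37 0.000047 0.247948 1.729730 25       42.52000 4.337004

major motifs: ['rGTCw', 'nrGTC']
```

The planted word tops the ranking: present in m = 20 of 25 cluster promoters
versus k = 32 of 80 genome-wide (2-fold enriched, p ≈ 10⁻⁶), with mean
position 44.7 of 56 valid starts (TSS-proximal, z ≈ 4.8). The position
filter absorbs the same-frame variants (`rGTCn`, `rGyCw`, …, which share the
planted starts) into the first major motif; `nrGTC` survives because a
one-step frame shift is a different position under the exact-start
convention. The same workflow is exposed on the command line:

```sh
motifindexer fixture --n-promoters 80 --window-length 60 --cluster-size 25 \
    --plant rGTCw:0.7:0.02 --tss-biased --seed 3 --out-prefix fx
motifindexer index --fasta fx.fasta --window-length 60 --word-length 5 --out fx_genome
motifindexer majors --fasta fx.fasta --cluster fx.cluster.txt \
    --genome-index fx_genome --window-length 60 \
    --pvalue-cutoff 1e-6 --relaxed-cutoff 1e-4 --stop-below 0 --out majors.tsv
```

Full-scale 8-mer indexing uses a dense 11⁸ counter array (~429 MB at 16
bits per oligo; the per-batch bit-packed transform adds ~1.7 GB transient),
so a genome-wide index fits on a desktop.

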