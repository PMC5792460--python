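# barcodekit

Evaluation toolkit for multi-locus DNA barcode reference libraries.

DNA barcoding assigns specimens to species by comparing short standardized
genomic regions against a reference library. Before such a library can be
used — for example to identify traded timber from anatomically
indistinguishable hardwood species — each candidate barcode locus and every
combination of loci must be scored for how reliably it separates the
species in the library. `barcodekit` implements that evaluation end to end
for anyone building or auditing a barcode reference library: wood
forensics, herbal-product authentication, biodiversity survey QC.

## What it computes

Given per-locus aligned FASTA files plus a specimen table (species,
voucher status, tissue, geographic region), the toolkit produces:

* **Locus profiles** — recovery rate, aligned/ungapped length, GC%,
  variable and parsimony-informative sites, gap-bearing columns.
* **Pairwise distances** under pairwise deletion, with two models:
  the Kimura two-parameter distance
  `d = -½ ln((1 − 2P − Q)·√(1 − 2Q))`, where `P` and `Q` are the
  transition and transversion proportions among compared sites, and the
  uncorrected p-distance `d = (ts + tv) / n`. Saturated or low-overlap
  pairs are flagged undefined and excluded from summaries.
* **Barcoding-gap reports** — intra- vs interspecific distance
  distributions, overlap, and the fractions beyond a cutoff (default 0.05).
* **Best match / best close match** identification: each sequence is
  queried against all others and scored correct / ambiguous / incorrect by
  the species of its minimal-distance neighbors; best close match rejects
  queries whose nearest neighbor exceeds a threshold (default: the 95th
  percentile of all intraspecific distances) as *no match*. Species with a
  single sequence are reported as singletons and excluded from the
  denominator.
* **Neighbor-joining trees** (deterministic tie-breaking, p-distance by
  default) with column-resampling bootstrap supports, scored by the strict
  discrimination criterion: a species counts as discriminated only when all
  its specimens form an exclusive cluster on the unrooted tree and at least
  one of them is a vouchered collection. The same scoring applies to any
  metadata label, e.g. geographic region.
* **Exhaustive combination ranking** — all 2^k − 1 locus subsets are
  concatenated (complete-case) and evaluated with both methods.
* **Diagnostic mini-barcode discovery** — alignment columns fixed for
  different states (gap included) between a species pair, merged into
  contiguous substitution/indel blocks.

A calibrated synthetic-library generator (K80 sequence evolution along
random species trees, specimen-level divergence, species-fixed indel
blocks, per-locus dropout) makes the whole pipeline testable without any
sequence download.

## Worked example

```python
from barcodekit import (default_config, simulate_library, distance_matrix,
                        summarize_pairwise, barcoding_gap, best_close_match,
                        intraspecific_threshold, MatchParameters, success_rate,
                        evaluate_combinations)

lib = simulate_library(default_config(seed=42))   # 6 species, 39 specimens, 4 loci
locus = lib.locus("ITS2")
m = distance_matrix(locus, "K2P")
s = summarize_pairwise(m, lib.specimens)
print(f"ITS2: {len(locus.rows)}/{len(lib.specimens)} specimens recovered")
print(f"mean intraspecific K2P = {s.intra_stats['mean']:.4f}")
print(f"mean interspecific K2P = {s.inter_stats['mean']:.4f}")
g = barcoding_gap(s, cutoff=0.05)
print(f"{g.frac_inter_above:.1f}% of interspecific distances > 0.05")
thr = intraspecific_threshold(s, 95)
bcm = best_close_match(m, lib.specimens, MatchParameters(threshold=thr))
print(f"best close match (threshold {thr:.4f}): {success_rate(bcm).success:.1f}% correct")
results = evaluate_combinations(lib)
print(f"top combination: {results[0].label} "
      f"(BCM {results[0].best_close_match_success:.1f}%)")
```

prints

```
ITS2: 26/39 specimens recovered
mean intraspecific K2P = 0.0201
mean interspecific K2P = 0.0714
59.4% of interspecific distances > 0.05
best close match (threshold 0.0307): 96.2% correct
top combination: ITS2+matK+ndhF-rpl32 (BCM 100.0%)
```

Read: the nuclear ITS2-like locus is the hardest to recover (26/39) but the
most divergent, so on its own it identifies 25 of 26 recovered specimens;
adding the two fast chloroplast regions lifts identification to 100%. The
per-query TSV written by the pipeline shows which specimen fails and why.

The same analyses run from the shell:

```sh
barcodekit run --seed 42 --out report/        # full bundle on the demo library
barcodekit simulate --seed 42 --out lib/      # just the synthetic library
barcodekit combos --metadata lib/specimens.tsv lib/*.fasta
barcodekit diagnose --metadata lib/specimens.tsv \
    --species species_01 species_02 lib/ndhF-rpl32.fasta
```

`run` writes locus profiles, distance matrices and summaries, gap
histograms, per-query match outcomes, Newick trees with bootstrap
supports, the ranked combination table, diagnostic blocks, a
region-clustering report, and a run log with seeds and timings.

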