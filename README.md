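# kspec

k-mer spectrum error correction for short sequencing reads, with a
ground-truth read simulator and a gain/precision/recall evaluation toolkit.

Short-read sequencers miscall roughly 0.1–1% of bases. Because a genome is
sampled many times over, a true genomic k-mer (length-k substring) recurs in
many reads, while a k-mer created by a miscall is rare. `kspec` exploits
this: it counts every k-mer of a read set, derives a count threshold that
separates rare ("weak") from recurrent ("solid") k-mers, locates the
per-read regions covered only by weak k-mers, and repairs them with minimal
base edits until every k-mer in the read is solid. It is aimed at people
preparing short-read data (shotgun or deep viral amplicon) for assembly,
variant calling, or haplotype reconstruction — and at people who want to
*measure* a corrector, since the whole evaluate-against-ground-truth
workflow is included and self-contained.

## Method

For a read r = (r₁, …, rₙ), let S_k(i) be its k-mer starting at position i
and kc(s) the k-count of k-mer s — its number of occurrences across all
reads (reverse-complement strands merged in shotgun mode). The pipeline has
four phases:

1. **k-mer counting** — exact hash-map counts, or a counting Bloom filter
   (array of saturating counters addressed by multiple seeded hashes; counts
   are never under-reported, so membership recall is 100%).
2. **Error threshold** — from the k-count frequency distribution f(v)
   (number of distinct k-mers with k-count v), which is bimodal: an error
   mass near v = 1 and a mode near coverage depth. The threshold t_er is the
   first minimum of f(v), or — for the discontinuous distributions of
   amplicon data — the end of the first sufficiently long run of consecutive
   zeros in f(v). A k-mer s is *weak* iff kc(s) ≤ t_er.
3. **Error regions** — maximal runs of read positions p with KC_k(p) ≤ t_er,
   extended by 1-D mean-shift clustering of the read's k-count profile
   (neighbouring positions whose counts cluster with the weak core join the
   region) and merged when overlapping.
4. **Correction** — *short* regions (≤ k positions, the footprint of one
   error) are fixed by exhaustive single-edit search: every substitution
   (optionally indel) in the region's base window is scored by the minimum
   post-edit k-count over the k-mers it touches, and only edits that make
   them all solid survive. *Long* regions are swept left to right, repairing
   the first weak k-mer at its rightmost base and re-scanning. Reads whose
   regions admit no solid-making edit are reported uncorrectable (optionally
   discarded or end-trimmed).

For amplicon data, corrected reads are collapsed by exact sequence identity
into a haplotype table with frequency estimates.

Evaluation compares applied corrections with ground truth per base: TP =
error restored to its true base, FN = error missed or wrongly replaced,
FP = correct base altered, TN = untouched correct base, and

    gain = (TP − FP) / (TP + FN)      precision = TP / (TP + FP)
    recall = TP / (TP + FN)           F = 2·P·R / (P + R)

Gain is 1.0 for a perfect run and negative when a corrector does more harm
than good.

## Worked example

Simulate a 3 kb genome at 30× coverage with 0.5% substitution errors,
correct the reads against their own spectrum, and score the corrections
against the simulator's ground truth:

```
$ kspec simulate --genome-length 3000 --coverage 30 --read-length 80 \
      --sub-rate 0.005 --seed 3 --out-prefix sim
wrote 1125 reads (501 planted errors) to sim.fastq

$ kspec correct --in sim.fastq --k 13 --out corr.fastq \
      --tef applied.tef --log log.json
t_er=4 (first_minimum); corrected=396, unchanged=720, uncorrectable=9, discarded=0, total_edits=495

$ kspec evaluate --truth sim.tef --applied applied.tef --reads sim.fastq
{
  "TP": 495,
  "FP": 0,
  "FN": 6,
  "TN": 89499,
  "gain": 0.9880239520958084,
  "precision": 1.0,
  "recall": 0.9880239520958084,
  "f_score": 0.9939759036144578,
  ...
}
```

Reading the output: the threshold detector put t_er at 4, so k-mers seen at
most 4 times are treated as erroneous; 495 of the 501 planted errors were
restored to the true base (TP) with no correct base altered (FP = 0), giving
gain 0.988 at precision 1.0. The same operations are available as library
functions (`kspec.simulate_reads`, `kspec.correct_dataset`,
`kspec.evaluate`); the CLI is a thin wrapper.

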