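# Methods

## Model and assumptions

The corrector rests on the standard k-spectrum argument. If a genome of
length L is sequenced to depth c with reads of length ℓ and per-base error
rate e, a genomic k-mer is expected to appear about c·(ℓ−k+1)/ℓ·(1−e)^k
times, while a k-mer created by a miscall appears once (or a handful of
times when the same miscall recurs). The k-count frequency distribution
f(v) is therefore bimodal, and a count threshold t_er in the valley
classifies k-mers as weak (≤ t_er, presumed erroneous) or solid. The
assumptions that matter:

- coverage is high enough (≳ 15–20×) and errors rare enough that the two
  modes of f(v) do not overlap appreciably;
- k is large enough that random k-mer collisions are rare (the helper
  `suggest_k` returns ⌈log₄ L⌉, the smallest k whose k-mer space is at
  least the genome size) but small enough that most read windows are
  error-free;
- low-frequency *true* variation (rare haplotypes, contaminants) is
  indistinguishable from error below t_er — such reads come out
  "uncorrectable" or are corrected toward the majority sequence.

Correction treats the spectrum and t_er as frozen: edits never feed back
into the counts, so output is deterministic and independent of read order.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 15 | window length; 4¹⁵ ≈ 10⁹ exceeds bacterial genome sizes, and 15-mers still leave most 100 bp windows error-free at e ≤ 1% |
| `threshold_method` | `first_minimum` (shotgun), `zero_run` for amplicons | the first-minimum rule needs a smooth valley; amplicon k-count distributions are discontinuous, where the zero-run rule is the natural reading |
| `min_zero_run` | 3 | minimum length of the zero run ending at t_er; 3 suppresses single-gap noise in small histograms. The run length is a genuine free parameter of the rule |
| `canonical` | true (shotgun), false (amplicon) | shotgun read strand is arbitrary, so a k-mer and its reverse complement share a count; amplicon sequencing is strand-specific |
| `short_region_budget` | 2 edits | a short region is the footprint of one error; the budget is a safety net for the rare double hit |
| long-region cap | 2 × region length | bounds work and guarantees termination of the greedy sweep |
| `bandwidth` | max(2, MAD of the read's k-counts) | mean-shift window; the median absolute deviation adapts to the read's coverage spread with a floor that keeps integer counts from fragmenting |
| Bloom filter | 4 hashes, 8-bit counters, `sized_for(n, 1%)` | classic m = −n ln p/ln²2 sizing; counters saturate rather than wrap so reported counts never fall below the truth |
| `min_frequency` (haplotypes) | 0.001 | reporting floor; haplotypes below it are aggregated into an explicit remainder |

## Threshold detection details

f(v) is always evaluated on a zero-filled integer axis 1..max(v): the
zero-run rule is meaningless on a sparse map. `first_minimum` returns the
smallest v with f(v) ≤ f(v+1); a monotone-decreasing histogram has no
interior minimum and degrades to t_er = 0 with an explicit warning flag
(only never-seen k-mers weak). `zero_run` returns the last v of the first
zero run of length ≥ `min_run_length` and falls back to `first_minimum`
when no qualifying run exists — on well-covered shotgun data the valley
often contains sporadic repeat and recurrent-error k-mers, so the fallback
is the common path there, which is why it is the shotgun default to begin
with. No smoothing is applied before minimum detection (a config option
could add it; raw f(v) is the primitive).

## Region discovery and clustering

Weak-run discovery is exact. The mean-shift step uses a fixed-bandwidth
flat kernel in one dimension: each point iterates x ← mean{y : |y−x| ≤ h}
to a fixed point (tolerance 1e−6, ≤ 500 iterations — integer-valued count
data converges in a handful of steps), and converged modes within h/2 of
each other share a cluster. A variable-bandwidth formulation would adapt to
unequal coverage strata, but at read scale (≤ a few hundred points, integer
counts) the fixed-h version is exactly verifiable against an
exact-arithmetic oracle, which the test suite does. All k-mer positions of
the read are clustered, not only those near weak runs. Extension grows a
segment while the adjacent position's label matches the label of *any*
position already in the grown segment (fixed-point iteration — the more
permissive reading of growth); regions that then overlap or touch are
merged. k-mers containing N are never counted, never weak, and break runs.

## Correction details

Candidate edits are confined to a region's base window [start, end+k−1] and
scored by (minimum, total) post-edit k-count over the k-mers overlapping
the edited base; a candidate survives only if that minimum clears t_er.
Ranking is totally ordered — higher minimum, then substitution before
indel, higher total, leftmost position, alphabetical base — so correction
is deterministic without any random seed. For long regions only the k-mers
up to the first weak start are required to clear the threshold (later
windows may contain further errors that subsequent iterations repair).
Insertions into the quality string get quality '#'; applied-edit positions
are mapped back to original-read coordinates through an origin map so the
output TEF lines up with simulator truth even under indels. Uncorrectable
reads keep their sequence by default (`discard_policy="keep"`); dropping
them and trimming weak read ends (≤ k−1 bases per side, only bases that
participate in no solid k-mer) are explicit options, off by default.

TEF edit types always name the *sequencing error*: a base the corrector
deletes is recorded as an insertion error and vice versa, which makes truth
and applied records directly comparable.

## Evaluation

Substitution-only evaluation is positional: TP/FN/FP/TN per base as defined
in the README, with the partition TP+FP+FN+TN = Σ read lengths enforced by
construction. A wrong replacement counts FN only (the base was already
wrong, so no appropriate base was modified); this is a declared convention
— other toolkits may count it FP as well. Undefined ratios are NaN plus an
explicit flag, never 0, so averaging across datasets cannot silently
inflate. When corrections change read length, positional matching is
ill-defined; `classify_by_alignment` instead aligns original and corrected
read to the true read (unit costs, leftmost-optimal path via edlib) and
attributes errors to true-read coordinates. The context profiler takes
error-centred tuples from the *reference*, not the reads (neighbouring read
bases may themselves be miscalls), and builds its background from each
read's reference span padded by 6 bases, mirroring the read sampling to
avoid GC coverage bias; reverse-strand tuples are reverse-complemented into
read orientation.

## What the simulator emulates — and what it does not

The simulator generates i.i.d. random genomes at a chosen GC content,
uniform linear read sampling (single or paired), fair-coin strand choice,
uniform per-base substitutions to a uniformly chosen different base, and
optional indels (split evenly, spurious base inserted before a true one or
a true base dropped); truth records are exact and in as-sequenced read
coordinates. It does **not** model platform-specific behaviour: no
homopolymer-length errors, no quality-correlated or position-dependent
error rates (qualities are constant Q40 by default), no PCR amplification
bias, no coverage waviness, no chimeras. Passing tests therefore
demonstrate correctness of the algorithmic chain under the spectral model's
own assumptions, not performance on any particular instrument's data, where
error clustering and biased coverage will erode gain before anything else.

## Problem sizes used by the test suite

The behavioural tests run simulations sized to exercise the statistics
without waste: threshold separation on a 10 kb genome at 30× with 1%
errors; end-to-end correction on 10 kb at 50× with 0.5% errors (gain ≥ 0.7,
precision ≥ 0.9 asserted; the run itself achieves ≈ 0.98 / 1.0); idempotence
and soundness on 5 kb at 30×; amplicon recovery with five 300 bp haplotypes
at frequencies 0.50/0.25/0.15/0.09/0.01, pairwise 5–11 substitutions apart,
3000 reads at 0.3% error. Idempotence is asserted on the tool's corrected
output with uncorrectable reads discarded — re-feeding reads the tool
already declared unfixable measures the declaration, not the fixed point.

## Known limitations

- Exact counting holds the whole spectrum in memory; the Bloom backend
  trades memory for overcounts but cannot tabulate f(v) directly — a
  one-pass instance-weighted estimate (instances at count v divided by v)
  stands in, and is noisier exactly where the threshold lives.
- Candidate search is single-edit-at-a-time; two errors within one k-mer
  window defeat the strict all-solid survival rule and usually surface as
  "uncorrectable" rather than a wrong fix (visible as FN, not FP).
- Haplotype collapse is exact string identity; residual uncorrected errors
  fragment a true haplotype into satellite rows rather than merging them.
- Rare haplotypes whose private k-mers fall near t_er can be partially
  absorbed into the majority sequence — at 1% frequency and 3000× this
  shows up as under-estimation, visible in the amplicon test.
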