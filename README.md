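# tdcrawl

Rank-dependent, PWM-free alignment of k-mers carrying quantitative binding
metrics.

High-throughput in vitro protein–DNA binding assays (SELEX-seq, protein
binding microarrays, SMiLE-seq) yield highly reproducible binding metrics at
the level of the k-mer — but a k-mer usually covers only part of a
transcription factor's binding site, and knowing *which* part requires an
alignment. `tdcrawl` implements the Top-Down Crawl: an ultra-rapid greedy
alignment that depends only on the **rank order** of the metrics, so it needs
no position weight matrix, no motif discovery and no experiment-specific
parameterization. It is aimed at anyone turning k-mer enrichment tables into
positionally resolved models of TF–DNA recognition.

## The algorithm

Given k-mers $s_1, \dots, s_n$ with binding metrics $E_1 > E_2 > \dots$:

1. The k-mer with the largest metric is assigned shift $\delta = 0$ and
   becomes the first **reference**.
2. Every unaligned k-mer at Hamming distance 1 from the reference joins the
   alignment at the reference's shift.
3. Every unaligned k-mer overlapping the reference by $k-1$ or $k-2$ bp joins
   at the reference's shift $\mp d$ ($d \in \{1, 2\}$): a k-mer whose last
   $k-d$ bases equal the reference's first $k-d$ bases extends the 5′ end and
   gets $\delta_{\mathrm{ref}} - d$; the mirror case gets
   $\delta_{\mathrm{ref}} + d$. For example, `AGTAAAC` overlaps the 5′ end of
   `GTAAACA` and is assigned $\delta = -1$.
4. The reference is marked complete; the next reference is the
   highest-metric aligned-but-not-complete k-mer. The crawl stops when every
   aligned k-mer has served as reference. Shifts are never revised.

Companion tools close the loop with PWM-based methods: a metric-weighted PWM
can be built *from* a crawl alignment (the logo-style summary), any external
PWM can be padded with neutral columns and used to align k-mers by best
log-odds placement, and two alignments can be compared by their
origin-reconciled shift agreement. Alignment quality is scored the standard
way: elastic-net multiple linear regression predicting log enrichment from
one-hot bases plus minor groove width and electrostatic potential along the
aligned window, under 5-fold cross-validation, reporting the median held-out
$R^2$.

## Worked example

```sh
$ printf 'GTAAACA\t9.0\nAGTAAAC\t5.0\nTAAACAG\t4.5\nGTATACA\t3.0\n' > input.tsv
$ tdcrawl align input.tsv --out aligned.tsv
aligned 4 k-mers (k=7) -> aligned.tsv
$ cat aligned.tsv
_GTAAACA_	0	9.0
AGTAAAC__	-1	5.0
__TAAACAG	1	4.5
_GTATACA_	0	3.0
```

`GTAAACA` has the largest metric, so it seeds the alignment at shift 0.
`AGTAAAC` shares its last six bases with the reference's first six — a 5′
overlap — and lands at shift −1; `TAAACAG` is the mirrored 3′ overlap at +1;
`GTATACA` is a single-base mutant of the reference and inherits shift 0.
Gaps are written as `_`, one column per bp of shift range.

The same machinery is available as scikit-learn style estimators:

```python
>>> from tdcrawl import TopDownCrawlAligner
>>> aligner = TopDownCrawlAligner().fit(
...     ["GTAAACA", "AGTAAAC"], [9.0, 5.0])
>>> aligner.shift_of_
{'GTAAACA': 0, 'AGTAAAC': -1}
```

A full synthetic round trip — simulate a SELEX-like table from a known
additive binding-energy model, align it, summarize it as a PWM, re-align
against that PWM and compare, then score the alignment by regression:

```sh
$ tdcrawl simulate --core-width 8 --k 10 --noise 0.01 --n-background 2000 \
      --seed 11 --out sim.tsv --truth truth.tsv
simulated 3771 k-mers (consensus AATTCCAA) -> sim.tsv
$ tdcrawl align sim.tsv --out sim_aligned.tsv
aligned 1879 k-mers (k=10) -> sim_aligned.tsv
$ tdcrawl logo sim_aligned.tsv --out pwm.meme --max-shift 5 --exp-metrics
PWM (width 20, consensus TAACAAAATTCCAAGCGGAG) -> pwm.meme
$ tdcrawl pwm-align pwm.meme sim.tsv --out pwm_shifts.tsv
$ tdcrawl compare sim_aligned.tsv pwm_shifts.tsv
{
  "agreement": 0.9717935071846727,
  "reconciliation_offset": 5,
  "n_eligible": 1879
}
$ tdcrawl evaluate sim_aligned.tsv --out metrics.json --seed 17 --zscore 1
median R^2 = 0.8202 over 60 k-mers -> metrics.json
```

97% of crawl-aligned k-mers are re-assigned the same shift by the PWM built
from the alignment itself, and an elastic-net model over the aligned window
explains ~82% of the held-out variance in log enrichment of the significantly
enriched k-mers — both signs of a consistent registration. Every subcommand
writes a `<output>.run.json` sidecar recording the version, configuration and
input checksums.

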