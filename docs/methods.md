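# Methods

## Scope and model

`tz4c` analyses viewpoint-based chromatin-contact profiles at fragment
resolution: per restriction fragment, the number of sequencing reads that
ligated to one anchor ("viewpoint") fragment. Its scientific target is the
role of CTCF-site arrangement at a contact-domain boundary, probed with
engineered deletion/inversion alleles. The package contains both the
analysis (annotation, processing, statistics) and a generator that emulates
such libraries, so the whole study runs synthetically and deterministically.

### Expected contact profile

The generator's expected weight for a fragment with midpoint at distance
`d` from the viewpoint is

    w ∝ (d + d0)^(−α) · Π_s t(s, direction)

where the product runs over barrier sites strictly between the viewpoint
and the fragment midpoint. Each site points either toward the telomere
("+") or the centromere ("−"). A traversal meets the **front** of a site
that points back toward the viewpoint and the **back** of a site that
points away; fronts transmit with probability `t_front`, backs with
`t_back`, constrained `t_front ≤ t_back` (the motif's facing side blocks
extruding cohesin at least as strongly). For a viewpoint left of a
divergent array pair (a "−" array then a "+" array), rightward crossings
accumulate `t_front` factors across the "−" array — strong attenuation —
which is what makes divergent arrays behave as a boundary. The viewpoint's
own fragment is set to zero weight and the vector normalized to sum 1.
Reads are a single multinomial draw of the library depth over that vector.

Assumptions and simplifications: attenuation is memoryless and
multiplicative (no explicit cohesin loading/release kinetics, no loop
anchors, no Hi-C matrix); contacts are counted per fragment, not per base
pair; no sequencing-error, mappability or PCR-duplicate model. One known
consequence, deliberately not patched: inverting an array can only decrease
or preserve transmitted contact seen from the far side under a
multiplicative rule, so mutant/viewpoint combinations whose measured
invasion *rises* through mechanisms like barrier redundancy are outside
this model. The isotropic folding of a viewpoint between the two arrays is
reproduced geometrically (the viewpoint sits between the arrays), not
mechanistically.

### Default synthetic locus

A 900-kb span (`chrS`), digested on a deterministic 2-kb grid with every
engineered breakpoint added as a cut site, so alleles stay representable on
the fragment grid. A regular grid is used rather than random spacing
because contact weights are per fragment: uneven cut density near a
viewpoint would bias the left/right read sums by fragment count alone, and
the locus geometry is a fixed study condition, not a random variable.

The boundary (transition zone, 450–520 kb) carries two divergent CTCF
arrays:

| site  | position | orientation | t_front | t_back | occupancy | direct |
|-------|----------|-------------|---------|--------|-----------|--------|
| TZ-L1 | 455 kb   | −           | 0.3     | 0.8    | 0.9       | yes    |
| TZ-L2 | 463 kb   | −           | 0.3     | 0.8    | 0.9       | yes    |
| TZ-ES | 471 kb   | −           | 0.85    | 0.95   | 0.1       | no     |
| TZ-R1 | 495 kb   | +           | 0.3     | 0.8    | 0.9       | yes    |
| TZ-R2 | 503 kb   | +           | 0.3     | 0.8    | 0.9       | yes    |
| TZ-R3 | 511 kb   | +           | 0.3     | 0.8    | 0.9       | yes    |

Transmissions, `α = 1.0`, `d0 = 2 kb`, depth 2·10⁵ reads and 3 replicates
per library are calibration choices for a locus of this size, not measured
values: they give wild-type inter-domain leakage of a few percent and
clearly separated engineered-allele effects at realistic 4C depths.

Viewpoints: `VP-Tfap2c` (155 kb, exclusion 10 kb), `VP-Tdom` (430 kb,
exclusion 15 kb — the flank modeled as poorly mappable), `VP-TZmid`
(483 kb, 10 kb), `VP-Bdom` (540 kb, 10 kb). `VP-Tdom` sits 25 kb left of
the first "−" site so its 200-kb windows span the arrays; `VP-TZmid` is
equidistant (12 kb) from the innermost site of each array, making its
expected left/right attenuation nearly symmetric. Alleles: `Hap` (none),
`del1` (165–450 kb), `del2` (450–520 kb, both arrays), `del3`
(520–600 kb), `del-L`/`inv-L` (450–468 kb), `del-R`/`inv-R` (487–520 kb).
Analysis areas: Tfap2c-cen [0, 155 kb), Tfap2c-tel [155, 450 kb), TZ
[450, 520 kb), Bmp7 domain [520, 900 kb). Invasion/control pairs per
viewpoint: the adjacent domain beyond the boundary vs the viewpoint's far
side out to the locus end (e.g. `VP-Tdom`: [520, 900 kb) vs [0, 414 kb)).

### Seeding

One master seed; each consumer (library, ChIP dataset, sequence,
enrichment table) derives its generator from `SeedSequence([master,
sha256(label) mod 2³¹])` where the label encodes (purpose, allele,
viewpoint, replicate). Adding a library never shifts another's stream, and
every output is reproducible byte-for-byte.

## Analysis procedures

* **Coordinates** are 0-based half-open everywhere (BED convention).
* **Allele liftover**: deletion `[a,b)` unmaps interior points and shifts
  points right of `b` left by `b−a`; inversion reflects interior points to
  `a+b−1−x`. Targets are expressed in reference coordinates and may not
  overlap, which makes the composition order-independent; interval liftover
  clips deleted portions. Rearranged fragment maps require breakpoints on
  fragment boundaries (the generator guarantees this; re-digesting real
  data is out of scope).
* **Fragment-to-interval assignment** uses the fragment midpoint
  (`mid ∈ [start, end)`), a deterministic, order-free rule for fragments
  straddling interval edges.
* **Viewpoint exclusion** masks fragments whose midpoint lies within the
  exclusion radius on either side; masks accumulate and are idempotent.
  Statistics skip masked fragments but keep their counts.
* **RPM** divides by the library's total raw reads *before* masking:
  library size is a sequencing fact, and a mask-independent denominator
  keeps tracks comparable across alleles.
* **Smoothing** is a centered 11-fragment running mean in fragment order,
  truncated at the edges, with masked fragments removed from numerator and
  denominator. It exists for visualization only; all statistics consume
  raw masked counts (the summaries are scale-free ratios, and smoothing
  would correlate adjacent fragments).
* **Consensus CTCF sites**: merge peaks across datasets (book-ended
  intervals coalesce, matching common BED-merge semantics), count support
  as the number of datasets with ≥1 bp overlap (each dataset at most
  once), keep support ≥ k. Orientation is the strand of the best PWM
  log-odds over a 200-bp window centered on the peak midpoint; an exact
  cross-strand tie is reported as ambiguous rather than broken
  arbitrarily. A single PWM input is used (with a count-matrix mode,
  pseudocount 0.25, uniform background); ensemble voting over multiple
  PWMs is out of scope.
* **Direct vs indirect/weak binding**: a site is "direct" when mean
  CTCF-channel enrichment is ≥ 3× the mean IgG enrichment (and exceeds
  it); the threshold is this package's explicit operationalization of a
  qualitative wet-lab dichotomy and is configurable.
* **Permutation test**: statistic mean(B) − mean(A); all C(n_A+n_B, n_A)
  reassignments enumerated when ≤ 20 000, otherwise 10⁴ seeded Monte-Carlo
  draws with the observed assignment included. Ties count as "as extreme"
  and the observed assignment is always included, so p > 0; the resolution
  floor 1/#reassignments is reported alongside (with n = 3+3 the smallest
  achievable p is 1/20 = 0.05).
* **ANOVA + Tukey**: one-way fixed-effects F test and Tukey's HSD via the
  studentized-range distribution; pairs against the reference allele are
  reported first. Zero-residual-variance input is handled explicitly
  (F = 0, p = 1 when all groups are one constant).
* **Directionality window** (200 kb per side) is clipped at the modeled
  span without renormalization — the window size is chosen to stay inside
  the domains in the first place.

## Problem sizes

The default study is 452 fragments × up to 8 alleles × 4 viewpoints × 3
replicates at 2·10⁵ reads; the full pipeline (simulate → annotate →
profile → stats → compare) takes a few seconds. Decay-exponent recovery
uses one library at 10⁶ reads; the permutation-null calibration uses 2 000
simulated 3-vs-3 tests.

## What the synthetic world does and does not show

The generator realizes the phenomena the statistics are designed to
measure — orientation-dependent blocking, boundary loss on array deletion,
sign structure of directionality — so passing tests demonstrate that the
pipeline's counting, liftover and inference are correct and that the
statistics separate those effects at realistic depths. They do not
validate the barrier model against real chromatin: real 4C libraries have
mappability gaps, fragment-length biases, trans contacts, replicate-level
biological variability far above multinomial noise, and boundary effects
(e.g. increased invasion after inverting an array, seen from the far side)
that a multiplicative transmission rule cannot produce. Orientation
scanning is also sensitive to peak-midpoint shifts: a spurious peak
merging into a true site's interval can move the 200-bp scan window off
the motif, which is why peak-summit-based scanning is preferable when
summits are available.
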