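# tz4c

Quantifying how CTCF-binding-site arrangement controls the directionality of
chromatin folding at a contact-domain boundary, from viewpoint-based (4C-seq
style) fragment-level contact profiles.

## The problem

Mammalian genomes fold into contact domains (TADs) whose boundaries often
carry arrays of CTCF-binding sites in *divergent* orientation. Under the
loop-extrusion model, cohesin stalls predominantly at CTCF motifs that face
the incoming complex, so a divergent array pair splits folding into two
directions and behaves as a boundary. Testing this requires engineered
alleles — deletions and inversions of individual CTCF arrays — and
statistics that summarize, per 4C viewpoint, how far and in which direction
chromatin contacts reach.

`tz4c` implements that analysis as a reusable pipeline:

* **Consensus CTCF annotation** — merge peak calls from many ChIP-seq
  datasets, keep sites supported by at least *k* of *D* datasets (default
  14 of 31), orient each by the best PWM hit on either strand of a 200-bp
  window, and classify direct vs indirect/weak binding from native-ChIP
  enrichment (CTCF/IgG fold ≥ 3 by default).
* **Allele coordinate algebra** — deletions and inversions as explicit
  operations with point/interval liftover and rearranged fragment maps.
* **Profile processing** — viewpoint exclusion (10 kb, 15 kb for poorly
  mappable flanks), reads-per-million normalization, 11-fragment running
  mean for browser tracks (BedGraph), raw masked counts for statistics.
* **Contact statistics** — for a masked raw-count profile:
  * invasion ratio `I = invasion reads / control reads` (reads beyond the
    boundary in the adjacent domain over reads on the viewpoint's own far
    side);
  * directionality score `D = (R − L)/(R + L)` over the read counts within
    200 kb on each side of the viewpoint (negative = centromere-biased);
  * four-area read percentages and the intra-domain tel/cen ratio.
* **Significance** — exact one-sided permutation test of each mutant allele
  against the wild type (all label reassignments enumerated at these
  replicate numbers, ties counted as extreme, resolution floor reported) and
  one-way ANOVA with Tukey's HSD for multi-allele proportions.
* **Synthetic locus generator** — an extrusion-inspired stand-in for
  sequencing libraries: power-law distance decay `(d + d0)^(−α)` attenuated
  multiplicatively by each CTCF barrier between viewpoint and fragment,
  with orientation-dependent transmission (front `t_front` ≤ back
  `t_back`), multinomial read sampling, plus synthetic multi-dataset peak
  BEDs, motif-planted sequence and enrichment tables.

## Worked example

Three wild-type (Hap), array-deletion (del-L) and boundary-deletion (del2)
replicate libraries from the left-domain viewpoint of the default synthetic
locus, with invasion ratios and directionality scores:

```python
from tz4c.synthetic_data import (
    default_sim_config, default_invasion_regions, simulate_library)
from tz4c.fourc_processing import exclude_near_viewpoint
from tz4c.contact_stats import (
    directionality_score, invasion_ratio, permutation_test_one_sided)
from tz4c.locus_model import liftover_interval

cfg = default_sim_config(seed=0)
alleles = {a.name: a for a in cfg.alleles}
vp = next(v for v in cfg.viewpoints if v.name == "VP-Tdom")
inv_ref, ctl_ref = default_invasion_regions()["VP-Tdom"]

ratios = {}
for name in ("Hap", "del-L", "del2"):
    allele = alleles[name]
    inv = liftover_interval(inv_ref, allele)
    ctl = liftover_interval(ctl_ref, allele)
    ratios[name] = []
    for rep in range(cfg.n_replicates):
        p = exclude_near_viewpoint(simulate_library(cfg, allele, vp, rep))
        r = invasion_ratio(p, inv, ctl)
        d = directionality_score(p)
        ratios[name].append(r.ratio)
        print(f"{name:6s} rep{rep}  invasion/control = "
              f"{r.invasion_count:>6d}/{r.control_count} = {r.ratio:.4f}   "
              f"directionality = {d.score:+.3f}")

test = permutation_test_one_sided(ratios["Hap"], ratios["del2"], "greater")
print(f"\ndel2 vs Hap one-sided permutation: statistic = "
      f"{test.statistic:.4f}, p = {test.p_value:.3f} "
      f"(floor 1/{round(1/test.min_p)})")
```

prints

```
Hap    rep0  invasion/control =   1703/84863 = 0.0201   directionality = -0.590
Hap    rep1  invasion/control =   1704/85056 = 0.0200   directionality = -0.592
Hap    rep2  invasion/control =   1703/84847 = 0.0201   directionality = -0.594
del-L  rep0  invasion/control =  17960/72568 = 0.2475   directionality = -0.201
del-L  rep1  invasion/control =  18118/72402 = 0.2502   directionality = -0.196
del-L  rep2  invasion/control =  17690/72193 = 0.2450   directionality = -0.200
del2   rep0  invasion/control =  58180/63945 = 0.9098   directionality = +0.000
del2   rep1  invasion/control =  58367/64204 = 0.9091   directionality = -0.001
del2   rep2  invasion/control =  58885/63573 = 0.9263   directionality = +0.010

del2 vs Hap one-sided permutation: statistic = 0.8950, p = 0.050 (floor 1/20)
```

Reading the numbers: with the intact divergent boundary only ~2 % as many
reads cross into the adjacent domain as stay on the viewpoint's own side,
and folding from the left-flank viewpoint is strongly centromere-biased
(D ≈ −0.59). Deleting one array (del-L) lets ~12× more contacts through;
deleting the whole boundary (del2) makes invasion comparable to the control
zone (I ≈ 0.91) and flattens directionality to ≈ 0. With three replicates
per group the exact permutation test bottoms out at its resolution floor
p = 1/20 = 0.05.

The same study runs end to end from a shell:

```sh
tz4c run-all --config my_config.yaml      # bundled default config if omitted
tz4c simulate | annotate-ctcf | profile | stats | compare   # stage by stage
tz4c validate-config my_config.yaml
```

producing per-library counts TSVs, BED peak sets, consensus-site BED6,
smoothed BedGraph tracks, a long-format `results.tsv`, a `tests.tsv` of
group comparisons, and a `manifest.json` of seeds, parameters and output
hashes. Re-running with the same config is byte-identical.

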