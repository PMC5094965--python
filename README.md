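# urocnv

Copy-number abnormality profiling of urine and plasma cell-free DNA
(cfDNA) from shallow whole-genome sequencing, for liquid-biopsy analysis
of advanced prostate cancer.

Tumor cells shed DNA into blood and — after renal filtration — urine. At
shallow sequencing depth, individual mutations are invisible, but
chromosome-arm-scale copy-number variation (CNV) still leaves a measurable
footprint in binned read counts. `urocnv` turns that footprint into a
per-sample tumor-burden statistic and treatment-response index:

* reads are counted in fixed **60 kb windows** (51,607 bins on the hg19
  primary chromosomes) and scaled to each sample's global mean;
* the per-bin **log2 ratio** of cfDNA to matched germline (PBMC) DNA
  cancels constitutional CNVs, and a loess fit removes GC bias;
* a **circular-binary-segmentation** style algorithm with a permutation
  acceptance test partitions each chromosome into constant-level
  segments; segments of ≤ 4 bins and segments within ±1 Mb of a
  centromere are excluded;
* the **genome abnormality score** (UGA in urine, PGA in plasma) is
  `Σ top-10 |segment mean log2|` — a proxy for the tumor DNA fraction;
* the **treatment-efficacy index** `TEff = log2(pre/post) × 100`
  summarizes score change under therapy (positive = abnormality
  declined);
* gene-locus calls (AR, PTEN, TMPRSS2, ERG, NOTCH1, MYCL, …),
  cross-sample **minimal-overlap regions**, direct pre/post
  treatment-change profiles, and **median-dichotomized Kaplan-Meier /
  log-rank** survival association complete the pipeline.

A synthetic-data module generates matched cfDNA/gDNA counts (negative
binomial, tumor-fraction mixture `1 + f·(cn−2)/2`, optional GC bias) with
known truth, so the whole pipeline is testable without any sequencing
data. See `docs/methods.md` for the model details and parameter table.

## Worked example

Simulate a castration-resistant-like sample carrying an AR-region gain at
tumor fraction 0.4, and run the scoring pipeline:

```python
import numpy as np
from urocnv import (call_gene_locus, filter_segments, gc_correct,
                    ratio_profile, scale_to_global_mean, segment_profile,
                    uga_score)
from urocnv.simulate import get_scenario, simulate_pair

sc = get_scenario("ar_gain", f=0.4, depth=150, seed=3)
gdna, cf, truth = simulate_pair(sc.truth, seed=3)

prof = gc_correct(ratio_profile(scale_to_global_mean(cf),
                                scale_to_global_mean(gdna)))
seg = filter_segments(segment_profile(prof, alpha=0.01,
                                      n_permutations=1000, seed=17),
                      min_bins=4)
score = uga_score(seg)
print(f"UGA score: {score.score:.3f} (k={score.k})")
call = call_gene_locus(seg, sc.loci[0])
print(f"AR locus: {call.status} (segment mean log2 = "
      f"{call.supporting_mean_log2:+.3f}, "
      f"expected log2(1+0.4) = {np.log2(1.4):+.3f})")
```

Output:

```
UGA score: 0.727 (k=10)
AR locus: amplified (segment mean log2 = +0.482, expected log2(1+0.4) = +0.485)
```

The simulated copy-4 gain diluted to tumor fraction 0.4 has expected log2
ratio `log2(1 + 0.4·(4−2)/2) ≈ +0.485`; segmentation recovers +0.482, the
locus is called amplified, and the gain dominates the top-10 score sum
(the remainder is segment-level noise from the 22 toy chromosomes).

A command-line interface mirrors the library stage by stage:

```sh
urocnv simulate --scenario ar_gain -f 0.4 --seed 3 --outdir sim/
urocnv normalize --cf sim/cf.counts.tsv --gdna sim/gdna.counts.tsv \
       --bins sim/bins.tsv --out profile.tsv
urocnv segment --profile profile.tsv --bins sim/bins.tsv --out segments.tsv
urocnv run --manifest manifest.tsv --clinical clinical.tsv --outdir out/
```

Every output header carries the configuration hash and seed; re-running
with the same configuration reproduces identical numeric columns.

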