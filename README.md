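# skelchip

Knockout-controlled ChIP-Seq analysis: peak calling against a matched
negative-control library with a Skellam null and local false discovery rate,
followed by Gibbs-sampling motif discovery, SELEX consensus construction,
positional affinity classification, and TSS-proximity annotation.

## The problem

ChIP-Seq for a transcription factor with no good mock control can use a
knockout (KO) animal as the negative control: immunoprecipitate with the same
antibody in wild-type (WT) and KO neurons, sequence both libraries, and ask
where the WT pulldown is enriched over the KO pulldown.  The statistical core
is the per-window difference of tag counts.  Tiling the genome with 240 bp
windows every 10 bp, let R and N be the WT and KO tag counts in a window.
Both are well approximated as Poisson, R ~ Pois(λ_R), N ~ Pois(λ_N), so the
difference D = R − N follows a Skellam distribution

    P(D = d) = e^{−(λ_R+λ_N)} (λ_R/λ_N)^{d/2} I_d(2√(λ_R λ_N)),

with I_d the modified Bessel function of the first kind of order d.  Unequal
library depths are absorbed by the mode shift of this null.  The observed
density of D over windows is the two-component mixture

    f(d) = p0 f0(d) + p1 f1(d),

where f0 is the Skellam null and f1 the density over truly bound windows.
The local false discovery rate fdr(d) = p0 f0(d) / f(d) is estimated by
plugging the empirical histogram in for f; the **critical difference** d0 is
the smallest d ≥ 1 with fdr(d) ≤ f_p (threshold 0.01).  Windows with D ≥ d0
are significant; their central 10 bp bins are unioned into peaks, peaks
within 100 bp are merged, and regions ≤ 20 bp are set aside as too short for
motif analysis.  At the empirically estimated rates λ_R = 0.15273 and
λ_N = 0.21607 per 240 bp window, d0 = 6 fragments.

Downstream modules cover the rest of the analysis: a ZOOPS Gibbs sampler
with an order-3 Markov background extracts the common binding motif from
peak sequences; a SELEX simulator and consensus builder reproduce the
in-vitro binding-site-selection analysis; each 10 bp site is classified as
High/Medium/Low predicted EMSA affinity from its per-position deviations
from the reference site (changes at positions 3/6/7/8 abolish binding,
changes at 1/9/10 impair it, positions 2/4/5 are free); and peaks are
positioned by signed distance from their center to the nearest annotated
TSS.  A synthetic-data module generates every input with serialized ground
truth so all of the above is testable against known answers.

## Worked example

Simulate a 200 kb genome with 20 planted binding sites and matched WT/KO tag
tracks at the library rates, then run the full pipeline:

```bash
skelchip simulate genome --seed 7 --out sim
skelchip run-all --wt sim.wt.bed --ko sim.ko.bed \
    --chrom-sizes sim.sizes.tsv --genome sim.fa --seed 7 -o analysis
```

which prints

```
d0=6 peaks=20 too_short=0 consensus=AAAGCGAGGC
```

and writes `analysis.peaks.tsv` (a peak table with location, nearest gene,
best motif instance, and affinity call per peak):

```
location  start  end    gene_symbol  motif       affinity
chrS      7635   7895                AAAGCGAGGC  High
chrS      11755  12005               AAAGCGAGGC  High
...
```

`analysis.log.txt` records every parameter and fitted quantity — here the
estimated per-window rates (`lam_r = 0.530`, inflated over the background
0.153 by the planted signal; `lam_n = 0.204`), the critical difference
`d0 = 6`, 506 significant windows, and the recovered consensus
`AAAGCGAGGC` — and `analysis.locfdr.tsv` holds the full audit table
(d, f0, f̂, fdr per histogram bin).  All 20 planted sites are recovered with
their exact motif instance and classified High affinity.

Library use mirrors the CLI:

```python
from skelchip import SkellamNull, fit_locfdr
from skelchip.synthetic_data import gen_window_counts

r, n, labels = gen_window_counts(10**7, pi1=1e-4, enrichment=5.0, seed=1)
model = fit_locfdr(r - n, SkellamNull(0.15273, 0.21607), p0=1 - 1e-4, f_p=0.01)
print(model.d0)   # -> 6
```

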