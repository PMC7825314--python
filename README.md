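# fourcis

Near-cis 4C-seq signal decomposition and interaction-peak calling, with the
matching dual-luciferase reporter statistics and a fully seeded
synthetic-data generator.

## What it does

4C-seq (circular chromosome conformation capture sequencing) measures how
often one chosen locus — the *viewpoint*, e.g. a gene promoter — touches
every other site in the genome. Close to the viewpoint (±2 Mb, "near-cis")
the signal is dominated by a smooth decay of contact frequency with
genomic distance; specific regulatory contacts (enhancer–promoter loops)
sit on top of that trend as localized enrichments. `fourcis` separates the
two by modelling the per-restriction-fragment signal as

```
S(x) = B + I · e^(−|x − x_v|/λ) + Σᵢ Pᵢ · e^(−(x − xᵢ)²/(2σ²))
```

a constant background `B`, an exponential decay of intensity `I` and
length `λ` from the viewpoint `x_v`, and `N` Gaussian peaks with
amplitudes `Pᵢ`, centers `xᵢ` and shared width `σ`. Peaks are called
significant by a one-sided Wald test on the fitted amplitude at
p < 0.0005 and can be intersected with enhancer/promoter BED tracks.

The pipeline consumes per-fragment counts (bedGraph) on a restriction
fragment map built by in-silico double digestion (DpnII `GATC` +
Csp6I `G^TAC`), applies the standard 4C fragment filters (blind fragments,
fragments < 40 bp, ±5 kb around the viewpoint) and normalizes to a fixed
near-cis total before fitting. A separate module computes relative
luciferase units (firefly/renilla, normalized to the empty vector) and the
allele-comparison battery (Welch t-test, Bartlett, Shapiro–Wilk) for
reporter assays. See `docs/methods.md` for the full model description.

Audience: groups analysing viewpoint-based chromosome-conformation data
(or benchmarking peak callers on simulated profiles) who want a small,
tested, scriptable implementation rather than a monolithic pipeline.

## Worked example

Simulate a 4-Mb region with three known loops, fit it, and annotate the
calls against an enhancer track:

```bash
fourcis simulate --length 4000000 \
    --peaks 2032000:150,1850000:100,2600000:50 --seed 7 --out demo
# wrote demo.bedgraph / .fragments.bed / .truth.json (29218 fragments, total count 1000719)

fourcis fit --profile demo.bedgraph --fragments demo.fragments.bed \
    --viewpoint chr_sim:1999001-2001000 --out demo
# decay: B=26.85 I=2662 lambda=50037.5 bp; sigma=3037.79 bp; 3 peak(s), 3 significant

fourcis annotate --fit demo.fit.json --track enhancers.bed --out demo.annotations.tsv
cat demo.peaks.tsv
```

```
center      amplitude   z           p   significant
1849871.7   529.018281  142.728882  0   1
2031843.98  804.017336  172.797197  0   1
2599857.39  263.873551  71.0094597  0   1
```

All three injected loops are recovered within ~150 bp of their true
centers and the decay length within 0.1% (λ̂ = 50 037 bp vs 50 000
simulated). Amplitudes are in normalized units — the in-window total is
scaled to 10⁶, so fitted `B`, `I`, `P` are the truth values times the
normalization factor; `λ`, `σ` and the centers are scale-free. The peak
table columns are the fitted center (bp), amplitude, Wald z-score,
one-sided p-value and the p < 0.0005 flag.

The same pipeline is available as a scikit-learn-style estimator:

```python
from fourcis import FourCPeakCaller, io, GenomicInterval

profile = io.read_profile_bedgraph("demo.bedgraph", GenomicInterval("chr_sim", 1999000, 2001000))
fmap = io.read_fragment_map_bed("demo.fragments.bed")
caller = FourCPeakCaller(alpha=0.0005).fit(profile, fmap)
caller.decay_.lam      # fitted decay length, bp
caller.peaks_          # list of Peak(center, amplitude, z, p, significant)
caller.predict(x)      # model signal at coordinates x
```

Reporter statistics, from a TSV of firefly/renilla wells:

```bash
fourcis reporter-stats --table assay.tsv
# {"welch_t": 8.807, "welch_df": 20.61, "welch_p": 1.99e-08,
#  "bartlett_p": 0.392, "shapiro_p_group_a": 0.66, ...}
```

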