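# toxconcord

**Multi-compound transcriptomic concordance analysis** — do structurally
related compounds induce the *same* gene-expression response?

When several candidate compounds (for example bisphenol A and its proposed
substitutes BPF and BPS, profiled in stem-cell-derived hepatocyte-like
cells) are screened on expression arrays at matched potency (e.g. the CYP3A
IC50), the scientific question is rarely about any single gene: it is
whether the compounds' deregulated gene sets and fold-change profiles
coincide more than chance allows. `toxconcord` packages the statistics
needed to answer that question, end to end:

* **Differential expression** per compound-vs-control contrast: per-probe
  log2 fold change, pooled-variance two-sample *t*, Benjamini–Hochberg FDR,
  and the standard call rule — *up* if fold change > 1.5 and adjusted
  *p* < 0.05, *down* if fold change < 1/1.5 and adjusted *p* < 0.05.
* **Overlap ratio** of deregulated gene sets over a universe of *N* probes.
  For two sets the statistic is *O·N/(n₁·n₂)* and for three sets
  *O·N²/(n₁·n₂·n₃)* — equivalently the observed intersection *O* divided by
  the intersection expected if each set of size *nᵢ* were drawn randomly and
  independently from the array (*E = n₁n₂/N* or *n₁n₂n₃/N²*). A value of
  1.0 means the overlap is exactly as large as chance predicts; a
  Monte-Carlo sampler of the independence null provides an exceedance
  probability, and a three-set Venn partition gives the region counts.
* **Concordance**: pairwise Spearman correlation of genome-wide log2
  fold-change profiles, with the conventional "< 2.2 × 10⁻¹⁶" p-value floor.
* **PCA** of samples over the 1000 highest-variance probes (mean-centered,
  unscaled) with percent variance explained.
* **IC50 estimation** from percent-of-vehicle-control concentration-response
  curves via the linear segment *f(x) = ax + b* bracketing the 50 % crossing
  ("not reached" when the curve never falls to 50 %).
* A **synthetic-data generator** that emulates the study design (≈20,000
  probes, control + 3 compounds × 4 replicates, a shared deregulated core
  with correlated effect sizes, private per-compound sets, Gaussian log2
  noise; monotone logistic dose-response curves) and emits exact ground
  truth, so the entire pipeline is testable by parameter recovery.

## Worked example

```python
import toxconcord as tc

cfg = tc.SimulationConfig(n_probes=20_000, shared_de_count=150, private_de_count=100,
                          effect_mean=1.5, effect_sd=0.8, effect_correlation=0.9,
                          noise_sd=0.25, seed=7)
matrix, truth = tc.generate_expression(cfg)

tables = {c: tc.de_table(matrix, c, "control") for c in ("BPA", "BPF", "BPS")}
for c, de in tables.items():
    print(c, "up:", (de["call"] == "up").sum(), "down:", (de["call"] == "down").sum())

up = {c: set(de.index[de["call"] == "up"]) for c, de in tables.items()}
observed = len(up["BPA"] & up["BPF"] & up["BPS"])
s = tc.overlap_ratio_threeway(*(len(v) for v in up.values()), observed, matrix.n_probes)
print(f"three-way up overlap: O={s.observed}, E={s.expected:.5f}, ratio={s.ratio:.1f}")

profiles = {c: de["log2fc"] for c, de in tables.items()}
r, p = tc.pairwise_concordance(profiles)
print("Spearman R(BPA,BPF) =", round(r.loc['BPA','BPF'], 3), "p", tc.format_p(p.loc['BPA','BPF']))

curve = tc.generate_dose_response(tc.DoseResponseConfig(true_ic50=50.0, noise_sd=5.0, seed=7))
res = tc.estimate_ic50(curve)
print(f"IC50 = {res.ic50:.1f} uM (segment a={res.a:.3f}, b={res.b:.1f})")
```

Output:

```
BPA up: 90 down: 83
BPF up: 79 down: 80
BPS up: 74 down: 80
three-way up overlap: O=25, E=0.00132, ratio=19006.3
Spearman R(BPA,BPF) = 0.479 p < 2.2e-16
IC50 = 53.8 uM (segment a=-0.391, b=71.0)
```

Reading the numbers: each compound deregulates 150–180 probes; 25 probes
upregulated by *all three* compounds against an expectation of 0.0013 under
independence gives an overlap ratio of ~19,000 — overwhelming evidence of a
shared transcriptomic signature. The genome-wide fold-change profiles
correlate at R ≈ 0.48 (profiles contrasted against a common control share
its sampling noise, so even null probes contribute ≈ 0.5 — see
`docs/methods.md`). The injected IC50 of 50 µM is recovered at 53.8 µM
from a noisy 6-point curve.

## Command line

```bash
toxconcord simulate --out-dir data --seed 1          # matrix + sheet + truth
toxconcord diffexpr --matrix data/matrix.tsv --samples data/samples.csv \
    --treatment BPA --out de_BPA.tsv
toxconcord overlap -N 20000 --gene-list up_A.txt --gene-list up_B.txt
toxconcord ic50 --curve cyp3a.csv
toxconcord run --matrix data/matrix.tsv --samples data/samples.csv --out-dir report
```

`toxconcord run` writes the full report bundle — DE tables, gene lists,
Venn regions, overlap summaries with Monte-Carlo exceedance p, concordance
matrices, PCA coordinates, IC50 table, and a `manifest.json` with the
configuration, seed, and SHA-256 checksums of every output.

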