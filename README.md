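# vipmut

Sequence context shapes where single base substitutions (SBSs) occur in the
human genome. One proposed biophysical driver is DNA charge transport:
oxidative stress ionizes the double helix, and the resulting electron hole
migrates along the stacked bases until it localizes at a site of low
**vertical ionization potential (vIP)** — the energy (in eV) needed to remove
an electron at fixed geometry — where it can trigger a substitution.
`vipmut` is a library and command-line tool for testing this hypothesis on
variant catalogues: it relates the vIP of a substituted base and its flanking
stack to how often, and how pathogenically, that context mutates.

It is aimed at researchers in mutational-spectrum analysis and DNA
biophysics who have (a) a genome FASTA, (b) gene models (GFF3/BED12),
(c) an SBS table with clinical annotations (VCF with `CLNSIG`, or TSV),
and (d) a table of per-motif vIPs from quantum-chemistry calculations or
experiment. A fully synthetic data generator is included, so every stage
can also be exercised — and its statistical power checked — without any
external data.

## The statistics at the core

For a motif *m* of length *k* (patterns `XN`, `NXN`, `NXNN`, `NNXNN`,
`NNXNNN`, where `X` marks the substituted base and `N` any flanking base,
read on the transcribed strand), the **normalized SBS frequency** in a gene
region is

ν(m) = [c_SBS(m) / Σ c_SBS] / [c_region(m) / Σ c_region],

the motif's share among observed substitutions divided by its share among
all positions of that region (CDS exon, intron, or UTR); ν = 1 means
"mutates exactly as expected from composition". Against the motif vIPs
*X* the package computes:

- the Pearson correlation *r* and the regression slope of ν on *X*;
- a non-linear correlation: fit *f(X) = a + bX⁻¹ + cX⁻² + dX⁻³* by least
  squares (linear in *a…d*) and take *r*_nonlinear = Pearson(*f(X)*, ν);
- significance via the Fisher z-transformation, *z* = atanh *r*, with the
  statistic *z*·√(n−3) against the standard normal (two-sided), and the
  analogous two-sample test for differences of correlations;
- the 5′–3′ **asymmetry** *r*(XN…N) − *r*(N…NX), comparing motifs that
  extend into the 3′ flank against their 5′ mirror images;
- the **pathogenicity contrast** Δν(m) = ν_pathogenic(m) − ν_benign(m)
  (pooling "likely" labels, excluding VUS), correlated against motif vIP
  and, per substitution type, against |ΔvIP| of the base change;
- transition/transversion ratios R per region and effect class.

Quintuplet and sextuplet vIPs are composed as the mean of their
overlapping quadruplet windows; a composition-only estimate (mean of the
single-base vIPs) is also provided. The built-in single-base table uses
the experimental values vIP(G)=8.20 < vIP(A)=8.42 < vIP(C)=8.85 <
vIP(T)=9.10 eV.

## Worked example

Generate a synthetic study in which low-vIP triplet contexts mutate more
(site rate ∝ exp(−β·vIP), β = 0.5 eV⁻¹), then recover the planted signal:

```python
from vipmut.synthetic import SynthConfig
from vipmut.study import generate_study, vip_frequency_correlation
from vipmut.frequencies import ts_tv

cfg = SynthConfig(seed=42, n_genes=20, n_sbs=10_000)
study = generate_study(cfg)
res, slope = vip_frequency_correlation(study, region="exon")
print(f"triplet vIP vs normalized SBS frequency (exon): "
      f"r = {res.r:.3f} (n = {res.n}, p = {res.p:.2e}), slope = {slope:.3f} per eV")
print(f"transition/transversion ratio R = {ts_tv(study.records).ratio:.2f}")
```

prints

```
triplet vIP vs normalized SBS frequency (exon): r = -0.826 (n = 64, p = 4.67e-20), slope = -0.416 per eV
transition/transversion ratio R = 1.97
```

The negative *r* over the 64 triplets says that low-vIP contexts carry
more substitutions than their abundance predicts — the planted
charge-transport-like signal — with the Fisher-z p-value rejecting the
null decisively; R ≈ 2 reflects the generator's 4:1 transition bias.

The same analysis runs from files via the CLI:

```sh
vipmut simulate --seed 42 --outdir sim/
vipmut report --genome sim/genome.fa --models sim/models.gff3 \
    --variants sim/variants.tsv --vip-table sim/vip_table.tsv --outdir out/
```

which writes `normalized_frequencies.tsv`, `correlations.tsv`,
`asymmetry.tsv`, `ts_tv.tsv`, `pathogenicity_vip.tsv`,
`pathogenicity_dvip.tsv` and a `run_log.json` reconciling records read,
used and skipped.

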