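# coexq

Co-expression ranking on expression profiles and qPCR relative
quantification, for expression studies of the kind common in plant
reproductive biology: a bulk RNA-seq tissue atlas (TPM) used to find
genes co-expressed with a gene of interest, followed by qPCR validation
of candidate genes across tissues and developmental stages.

## What it computes

**Δsum co-expression ranking.**  Each gene's TPM vector across tissues
is turned into a mean-normalized profile

    z(g, s) = (x(g, s) − m(g)) / m(g),   m(g) = mean_s x(g, s),

after eliminating genes with zero mean (expressed nowhere).  The
profile is scale-free: genes with large and small expression values
become directly comparable.  Genes are ranked against a query by the L1
profile distance

    Δsum(a, b) = Σ_s |z_a(s) − z_b(s)|,

with the query itself at Δsum = 0; the smallest Δsums mark the most
similar expression patterns.

**qPCR workflow.**  Standard-curve fits (Cq vs log10 dilution) give the
amplification efficiency E = (10^(−1/slope) − 1) × 100 %, with QC bounds
R² > 0.980 and 90 % ≤ E ≤ 110 %.  Relative expression uses 2^-ΔΔCt
normalized to the mean of three reference genes (e.g. *RCE1*, *TUA2*,
*YLS8*) with a calibrator sample, technical replicates averaged before
ΔCt, mean ± SEM over biological replicates, and one-way ANOVA with
Dunnett's many-to-one comparison against the calibrator (adjusted
p-values computed by deterministic multivariate-t quadrature; stars at
p < 0.033 / 0.002 / 0.0002 / 0.0001).

**Synthetic data.**  Seeded generators produce TPM matrices with
planted co-expression modules and Cq plates with known fold changes, so
the whole pipeline is testable without downloads (see
`examples/sim_tpm.yaml`, `examples/sim_plate.yaml`).

## Worked example

Rank genes against a query on the bundled toy matrix:

    coexq coexpr rank --matrix examples/toy_matrix.tsv \
        --query AT5G18690 --out ranking.tsv

`ranking.tsv`:

    rank	gene_id	dsum
    1	AT5G18690	0
    2	AT2G22900	0
    3	AT3G21190	0.427778
    4	AT4G37450	1.48662
    5	AT2G04850	2.91026
    6	AT1G49750	7.35238
    7	AT5G14380	9.72445

The query heads the list at Δsum 0.  AT2G22900 also has Δsum 0: its TPM
row is exactly half the query's, i.e. an identical *pattern* at half the
level — the scale-free normalization treats them as the same profile.
The all-zero gene in the file was removed by the zero-mean filter.

Simulate a qPCR plate with known fold changes and quantify it:

    coexq simulate plate --config examples/sim_plate.yaml \
        --out plate.csv --truth folds.tsv
    coexq qpcr quantify --cq plate.csv --target AGP24 \
        --calibrator anther_st12 --out results.tsv

`results.tsv` (true folds were 0.25, 0.5, 1, 2, 4):

    sample	mean_fold	sem_fold	p_adjusted	label
    pistil_st11	0.266528	0.00719859	3.44502e-13	****
    pistil_st12	0.525181	0.00547354	4.127e-10	****
    anther_st12	1.00005	0.00728524		
    pistil_st14	2.02563	0.0366735	1.67755e-10	****
    silique_st17	4.0017	0.0596127	2.24043e-13	****

Each row is a tissue's expression relative to the calibrator
(anther stage 12): `mean_fold` ± `sem_fold` over the three biological
replicates, with the Dunnett-adjusted p-value and star label for the
comparison against the calibrator (which itself gets no p-value).  The
estimates recover the simulated truth to within replicate noise.

Every command writes a `<out>.provenance.json` with the parameters,
package version and seed needed to reproduce its output byte-for-byte.

The same functionality is available as a library:

```python
from coexq import (load_tpm_matrix, drop_unexpressed, normalize_profiles,
                   rank_coexpressed)

z = normalize_profiles(drop_unexpressed(load_tpm_matrix("examples/toy_matrix.tsv")))
ranking = rank_coexpressed(z, "AT5G18690", top_k=50)
print(ranking.entries.head())
```

## Layout

    src/coexq/expression_io.py   TPM matrix I/O, validation, means, zero filter
    src/coexq/coexpression.py    normalized profiles, Δsum, ranking
    src/coexq/qpcr.py            standard curves, QC, 2^-ΔΔCt, SEM
    src/coexq/dunnett.py         ANOVA + Dunnett multivariate-t quadrature
    src/coexq/simulate.py        seeded TPM and Cq-plate generators
    src/coexq/cli.py             `coexq` command (coexpr/qpcr/simulate/plot)
    docs/methods.md              model, assumptions, design choices
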