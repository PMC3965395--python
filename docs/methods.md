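# Methods

## Model and procedure

`mircnv` tests, per chromosome and CNV type (Gain/Loss), whether miRNA
gene loci are over-represented inside de novo CNVs. The observed statistic
is the hit count H: the number of (CNV, gene) pairs whose closed 1-based
intervals share at least one base. A gene overlapped by two distinct CNVs
contributes two hits; the count of distinct genes is tracked separately as
`unique`. The mapping stage also reports, per chromosome, L1 (summed gene
length), L2 (union length of the CNVs, overlapping regions counted once,
computed by sort-and-sweep interval merging) and the ratios R1 = L1/G and
R2 = L2/G against the chromosome length G.

The null hypothesis is positional randomness: each CNV keeps its observed
length L but its start is uniform on {1, …, G−L+1}, so the CNV lies wholly
within the chromosome. Placements are independent across CNVs, and all
CNVs of one type on one chromosome are re-placed jointly in each
realization. The Monte Carlo p-value is the plain tail proportion
p = #{H_sim ≥ H_obs}/N. P-values across chromosomes are corrected with the
Benjamini–Hochberg step-up procedure and cells with adjusted p < α are
called enriched; the distinct genes they contain become candidates, which
a population-CNV (DGV-style) intersection splits into population-shared
and study-specific loci.

## Assumptions and design choices

* **Independent placements.** Simulated CNVs may overlap one another. This
  is what makes the exact convolution null valid, and on realistic data it
  is inconsequential: observed CNVs cover at most ~26 % of any chromosome,
  so mutual-exclusion corrections are second-order. A non-overlapping
  placement model would invalidate the convolution oracle and is not
  provided.
* **Overlap predicate.** `any` intersection (≥ 1 shared base) is the
  default; with ~100 bp genes and ≥ 1 kb CNVs it differs from full
  containment only when a CNV boundary falls inside a gene. Both modes are
  implemented (`overlap_mode="containment"`), and the containment null is
  stochastically below the intersection null.
* **Strand** is recorded but ignored: CNVs are unstranded dosage events.
* **Duplicate CNVs** identical on (chrom, start, end, type) are merged by
  default — the statistic counts distinct genomic events, not carriers —
  with patient provenance pooled so per-gene patient counts survive.
  `keep_duplicates` disables the merge for sensitivity analyses.
* **FDR family.** Adjustment is applied within each CNV type separately
  (Gain rows together, Loss rows together), over cells that have data; N/A
  cells are not tests. A `joint` family across both types is available.
  Significance uses strict inequality p_fdr < α.
* **p-value convention.** The plain proportion r/N matches the tail-area
  definition of the test; the positively biased (r+1)/(N+1) variant is
  available via `empirical_pvalue(..., add_one=True)` for users who need
  guaranteed-positive p-values.
* **Gene model.** miRBase-style GFF3 input keeps only
  `miRNA_primary_transcript` features, so each hairpin locus is one gene;
  mature `miRNA` products are ignored. BED input is converted from
  0-based half-open to the internal 1-based inclusive convention at the
  boundary (size = end − start + 1).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_realizations` | 10⁶ | Monte Carlo sample size per chromosome/type cell; the standard error of a tail probability p is √(p(1−p)/N) |
| `seed` | none | master seed; per-cell generators are spawned deterministically from it and recorded in output headers |
| `alpha` | 0.05 | FDR level for significance calls |
| `overlap_mode` | `any` | overlap predicate (see above) |
| `fdr_family` | `per-type` | BH family: per CNV type or joint |

## Exact null

For one CNV of length L the hit count is a piecewise-constant function of
the start, so its exact pmf follows from an event-point sweep over the
gene-boundary-shifted windows [g_start−L+1, g_end] (clipped to the legal
start range); a direct O(G) enumeration of every start provides an
internal cross-check. The total-H pmf is the sparse convolution of the
per-CNV pmfs, stored as {support → probability} so cost scales with the
support, not with G. Its mean equals the sum of per-pair overlap
probabilities, which is checked analytically in the tests. The exact path
(`fit(exact=True)`) is preferable whenever CNV counts per cell are modest;
the sampler exists for scale and for fidelity to the histogram-based
procedure.

## Synthetic data generator

`FixtureSpec`/`make_dataset` emulate the scale of the real problem: gene
loci drawn uniformly without mutual overlap with lengths uniform on
80–110 bp (the empirical size range of miRNA primary transcripts), and CNV
lengths log-uniform on 1 kb–1 Mb, matching the kb-to-Mb spread of de novo
CNV calls. A fraction q of CNVs per chromosome is forced to cover a
uniformly chosen gene (start uniform among the containing placements,
clamped to chromosome bounds); q = 0 reproduces the randomization null
exactly, so p-values on such data are calibrated by construction, and
q > 0 plants a detectable enrichment. The generator does **not** emulate
segmental-duplication hotspots, GC/gap structure, clustered miRNA loci,
or platform-dependent CNV boundary noise — passing tests therefore
demonstrate the statistic's correctness and calibration under positional
randomness, not robustness to those real-data confounders (a null that
respects hotspots would need a different placement model).

## Numerical choices and degenerate inputs

* Sampling is vectorized in chunks (~4×10⁶ interval evaluations per
  chunk) with per-CNV counts obtained by binary search on the sorted gene
  boundaries; memory stays bounded regardless of N.
* Convolved exact pmfs are renormalized once at the end to absorb
  accumulated float error; the pmf-sum invariant is enforced at 10⁻¹².
* A chromosome with CNVs but no genes yields a null concentrated at 0 and
  p = 1; an observed count beyond the simulated support yields p = 0 under
  the plain-proportion convention.
* Adjacent touching intervals merge without a gap in the union
  (closed-interval arithmetic), but adjacency is never overlap.
* Correlation of hits on R2 requires ≥ 3 chromosomes with data and
  non-zero variance in both variables; N/A rows are excluded.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the sampler at N = 10⁴–10⁵
realizations per cell on toy chromosomes (10 kb) and synthetic genomes
(30–50 Mb chromosomes, 10–20 genes, 10 CNVs per cell): large enough that
Monte Carlo error (≤ ~0.5 % on tail probabilities at N = 10⁴) is far below
every tolerance asserted, while a full analysis at the production default
N = 10⁶ remains a command-line flag away. Null calibration uses 200
regenerated datasets; power uses 100.

## Known limitations

* The null ignores genomic structure (see generator notes); enrichment
  calls on real data inherit that assumption.
* Monte Carlo p-values of 0 are reported as 0 (resolution 1/N); use
  `exact=True` or the add-one convention when downstream analysis cannot
  tolerate zero p-values.
* The bundled reference tables carry published summary statistics, not
  raw patient CNV coordinates, so the full re-mapping of that study
  requires user-supplied inputs and is exposed as an optional integration
  test.
* Gene-level burden scores, dosage weighting, and placement nulls masked
  by assembly gaps are out of scope.
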