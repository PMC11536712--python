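# bcrclone

Joint Bayesian BCR hyperclustering and tumour-clone assignment from
single-cell variant reads.

## The problem

In B-cell malignancies such as follicular lymphoma, bulk whole-exome
sequencing yields a set of tumour clones defined by somatic SNVs, while
single-cell RNA sequencing of the same tissue yields, per cell, (i) a
handful of UMI counts covering those SNV positions and (ii) the full-length
B-cell-receptor (heavy+light chain) sequence, a lineage barcode diversified
by somatic hypermutation.  Neither signal alone maps cells to clones: the
scRNA variant reads are too sparse per cell, and the BCR marks lineage but
not genotype.  `bcrclone` is for computational biologists who want to
combine the two — pooling variant reads across cells that share a BCR
lineage — to obtain confident cell-to-clone assignments, error-corrected
clone genotypes, and single-cell genotypes for downstream
genotype-to-phenotype analysis.

## The model

With N variants, M cells, K clones and L variable BCR positions:

* `Ω ∈ {0,1}^{N×K}` — input clone genotypes (e.g. from a bulk phylogeny
  tool), assumed error-prone: the latent true genotypes `C` satisfy
  `P(C_ik=1 | Ω_ik, ξ) = 1−ξ` if `Ω_ik=1` else `ξ`, with
  `ξ ~ Beta(κ₀, κ₁)`.
* `A_ij ~ Binom(D_ij, θ_i)` if the clone of cell j carries variant i, and
  `Binom(D_ij, θ₀)` otherwise, with Beta priors on `θ₀` (stray-read rate)
  and each `θ_i` (alternate-allele expression rate).
* Cells partition into *hyperclusters* under a Chinese Restaurant Process,
  `T_j | T_{−j} ~ CRP(α₀)`, `α₀ ~ Gamma(a, b)`.  Hypercluster q has a
  per-position nucleotide profile `B_{l,q} ~ Dirichlet(g)` generating the
  observed BCR sequences `X_{j,l}`, and one clone label
  `I_q ~ Uniform{1..K}` — all cells of a hypercluster belong to one clone.

Inference is by Gibbs sampling with exact conjugate conditionals, one
auxiliary cluster per cell move (profiles integrated out of the move via
Dirichlet-categorical conjugacy), and the Escobar–West auxiliary-variable
update for `α₀`.  Convergence is assessed with the multivariate potential
scale reduction factor over (θ₀, mean θᵢ, α₀); results come from the chain
with the highest marginal posterior score.  See `docs/methods.md`.

## Worked example

Simulate a small dataset with known truth, fit, and score it:

```bash
bcrclone simulate --scenario basic --seed 7 --cells 120 --variants 30 \
    --positions 60 --out demo/sim
bcrclone fit --alt demo/sim/alt.mtx --total demo/sim/total.mtx \
    --variants demo/sim/variants.txt --barcodes demo/sim/barcodes.txt \
    --bcr demo/sim/bcr.fasta --omega demo/sim/omega.tsv \
    --chains 2 --n-init 500 --block 300 --max-blocks 8 --seed 1 \
    --out demo/fit
bcrclone evaluate --fit-dir demo/fit --truth demo/sim/truth.json \
    --out demo/eval
```

The fit iterates 300-sweep blocks until the chains agree
(`... INFO block 7: MPSRF=1.000285 (threshold 1.0010)`), then reports

```
fit written to demo/fit (MPSRF=1.0002851419597503)
```

and `evaluate` prints

```json
{
  "assignment_accuracy": 0.7416666666666667,
  "genotype_accuracy": 0.8111111111111111,
  "hypercluster_ari": 1.0,
  "mean_assignment_entropy": 0.8137548744774377
}
```

Reading these numbers: the BCR lineage structure is recovered exactly
(adjusted Rand index 1.0 against the generating hyperclusters), and 74% of
cells land on their true clone.  At this deliberately tiny scale each cell
carries only ~0.3 variant reads across 30 positions, so a hypercluster
pools very little read evidence and the per-cell clone posterior stays
spread (mean entropy 0.81 of a possible ln 3 ≈ 1.10); at realistic sizes
(hundreds to thousands of cells, ~100 variants) assignment accuracy
exceeds 0.95 in read-rich regimes — see the benchmark below.

Fit outputs are plain TSV/JSON: `assignment_probs.tsv` (cells × clones
posterior), `assignment.tsv` (MAP clone and hypercluster per cell),
`genotypes.tsv` (corrected clone genotypes), `diagnostics.json`, and a
manifest with every seed and parameter.

For real data, `bcrclone fit` additionally accepts `--variant-table` to
apply the selection filters (somatic SNVs, or >3-fold tumour/normal
alternate-frequency increase, with at least one alternate read), and the
library exposes the building blocks (`read_counts`, `read_bcr`,
`select_bcr_positions`, `filter_variants`, `derive_hyperparams`,
`fit`, `evaluate_fit`, `hypercluster_hamming`, `genotype_dendrogram`).

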