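# episyn

Information-theoretic detection of epistatic (multiplicative)
interactions between genetic markers and a binary phenotype.

## The problem

Genome-wide association studies routinely screen markers one at a time,
but complex phenotypes are shaped by *interactions*: pairs (or larger
sets) of SNPs whose joint effect on disease status exceeds anything
their marginal effects predict. Fitting a logistic regression with all
interaction terms is hopeless at GWAS scale, so practitioners rank
candidate pairs with cheap dependence statistics. `episyn` implements a
family of such statistics with a known, quantitative connection to the
underlying model — plus the simulation benchmark, sample-size theory and
exhaustive pairwise scan needed to use them in practice.

The data model is a full logistic interaction model over binary markers
`X_1..X_d ∈ {±1}` (with `Pr(X_i = +1) = p_i`) and outcome `Y ∈ {±1}`:

    Pr(Y = 1 | x) = σ( β_∅ + Σ_S β_S Π_{i∈S} x_i ),

where a coefficient `β_S` on `|S| ≥ 2` is a cooperative (epistatic)
interaction. The central statistic is the **multivariate synergy**

    Syn(X_S; Y) = Σ_{∅⊂T⊆S} (−1)^{|S|−|T|} I(X_T; Y)      [nats],

which reduces to mutual information for `|S| = 1` and to the interaction
information `I(X_i,X_j;Y) − I(X_i;Y) − I(X_j;Y)` for a pair. For a
highest-order interaction `S` with small coefficients,

    Syn(X_S; Y) ≈ (1/8) β_S² Π_{i∈S} 4 p_i q_i ,

so the synergy ranks pairs by (squared) interaction strength — but is
*interfered* by the marginal-dependent factor `Π 4 p_i q_i`. The
**adjusted multivariate synergy** divides that factor out,
`AdjSyn = Syn / [(1/8) Π 4 p̂_i q̂_i] ≈ β_S²`, and detectably improves
pair recovery. A sample-complexity bound
`N ≥ (e²/(e−2)²) Ñ (log Ñ)²` with
`Ñ = (2^{2|S|+3}/δ²) log(max{2^{|S|+1},6}/ε)` prescribes how many
samples guarantee `|Ŝyn − Syn| ≤ δ` with probability `1 − ε`.

See `docs/methods.md` for the full account of the measures, the
samplers, and the numerical conventions.

## Worked example

```python
import episyn as ep

model = ep.InteractionModel(
    d=6,
    beta={(0,): 1.2, (2, 4): 1.8},   # one main effect, one interacting pair
    p=[0.3, 0.5, 0.2, 0.6, 0.8, 0.4],
)
data = ep.sample_independent(model, N=3000, seed=42)

exact = model.exact_joint((2, 4), include_outcome=True)
print(model.predicted_synergy((2, 4)))            # 0.1659
print(ep.synergy(exact, (2, 4)).value)            # 0.0877
print(ep.adjusted_synergy(exact, (2, 4)).value)   # 1.7134
print(ep.synergy(data, (2, 4)).value)             # 0.1005
print(ep.adjusted_synergy(data, (2, 4)).value)    # 1.9869

res = ep.SynergyScan.from_dataset(data).fit(measure="adjusted_synergy")
print(res.summary(k=3))
```

```
Pairwise interaction scan: 6 SNPs, 15 pairs scored
measure: adjusted_synergy (nats-based); coding: as-given; min distance: 0 bp
top 3 pairs:
snp_a snp_b          measure     value  n_complete ...
   X3    X5 adjusted_synergy 1.9869452        3000
   X1    X5 adjusted_synergy 0.0894240        3000
   X1    X3 adjusted_synergy 0.0638014        3000
```

The planted pair (X3, X5 in 1-based labels; β = 1.8 with skewed
marginals 0.2 and 0.8) tops the ranking by a factor ~20. The quadratic
approximation `(1/8)·1.8²·(4·0.2·0.8)(4·0.8·0.2)` = 0.166 overshoots the
true population synergy (0.0877) because β = 1.8 is outside the
small-coefficient regime, while the adjusted estimate (1.99 from 3000
samples, 1.71 in population) is on the `β² = 3.24` scale — rankings,
which are all that detection uses, are unaffected by the remaining bias.

The bound for estimating a pair synergy to `δ = 0.5` with 90% confidence:

```python
ep.n_tilde(2, 0.1, 0.5)   # 2243.6
ep.n_bound(2, 0.1, 0.5)   # 1912978.8
```

A CLI mirrors the library: `episyn simulate model|data`, `episyn bench`,
`episyn complexity`, `episyn scan` (supports the CSV genotype dialect
and PLINK bed/bim/fam, dominant/recessive/genotype-major codings, a
minimum inter-SNP distance filter, and Fisher's-exact enrichment of the
top pairs against a reference pair list).

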