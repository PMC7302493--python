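# plchron

Penalized-likelihood divergence dating with cross-validated smoothing,
relaxed-clock diagnostics, tree-based 1:1 ortholog filtering, and a
rate-heterogeneity simulator.

## The problem

*Isoetes* (quillworts) are classic "living fossils": morphologically
similar plants are known from Triassic rocks, yet molecular dating places
the crown of the extant species in the Cenozoic. Dating that crown is
numerically delicate. The crown group sits at the end of a ~350 Myr stem
branch that has accumulated almost no substitutions, while its sister
lineage (*Selaginella*) has accumulated several times more change since
their common ancestor. Semiparametric rate smoothing must then decide
whether the short crown branches reflect young ages or slow rates — and
the answer depends on the smoothing weight. This package re-implements
that analysis end to end so the behaviour can be studied on data with
known truth.

## The method

Given a rooted phylogram with branch lengths `b_k` (expected
substitutions/site), an alignment length `L`, and fossil calibrations,
penalized likelihood (PL) maximizes

    sum_k [ x_k ln(r_k t_k) - r_k t_k ]  -  lambda * Phi(r)

over node ages and per-branch rates, where `x_k = b_k L` is the expected
substitution count on branch `k`, `t_k` the branch duration implied by the
ages, and the additive roughness penalty

    Phi = sum_{k: parent edge j} (r_j - r_k)^2  +  Var(rates of root edges)

couples rates on neighbouring branches. `lambda -> 0` gives every branch
its own rate (ages become unidentifiable); `lambda -> inf` enforces a
strict clock. The smoothing weight is chosen by leave-one-terminal-out
cross-validation over a half-decade grid `10^-2 ... 10^6`, scoring each
pruned terminal's predicted substitution count by `(x - x̂)² / x̂`.
Confidence intervals come from nonparametric bootstrap: resampled
alignment columns, branch lengths re-estimated under GTR+G+I on the fixed
topology, each replicate re-dated.

Diagnostics centre on the effective/assigned rate ratio of a branch,
`rho = (b / t̂) / r̂`: the observed branch length over what the fitted rate
and duration predict. `rho << 1` on the stem branch at high smoothing is
the signature of a lineage-specific slowdown being overridden by the
tree-wide average rate.

Modules: `phylo_core` (rooted trees, newick/nexus I/O, MRCA, calibrations),
`alignment_stats` (FASTA I/O, site classes, completeness, concatenation,
bootstrap/subsample), `branch_lengths` (GTR+G+I pruning likelihood,
fixed-topology branch-length fitting), `pl_dating` (the PL engine, CV,
gradient checks, bootstrap dating), `diagnostics` (rho tables and sweeps,
lognormal QQ, phylogram contrasts), `orthology` (monospecific-clade
pruning, 1:1 orthogroup extraction, occupancy and monophyly filters),
`synthetic_data` (chronogram/rate/alignment simulation with named
chloroplast-like and nuclear-like presets), `pipeline` (the `plchron` CLI).

## Worked example

```python
import plchron as pc

# a dating problem with known truth: ingroup crown at 50 Ma on a long,
# nearly substitution-free stem, erratic branch rates (chloroplast-like)
bundle = pc.paper_scenario("chloroplast-like")
rated = pc.apply_rates(bundle.chronogram, bundle.scenario, seed=3)
phylogram = pc.to_phylogram(rated, bundle.L, mode="poisson", seed=3)

sweep = pc.smoothing_sweep(
    phylogram, bundle.calibrations, bundle.L, pc.INGROUP_TAXA, seed=1
)
print(sweep[sweep["lambda"].isin([0.01, 1.0, 100.0, 1e6])])
```

prints (crown truth: 50 Ma)

```
        lambda         age  converged  gradient_check
0         0.01  153.276150       True           False
4         1.00  433.600108       True            True
8       100.00   28.970406       True            True
16  1000000.00   25.664115       True            True
```

Weak smoothing dates the crown several-fold too old (the model parks the
misfit on the stem; at the weakest settings the estimate sits on a ridge
and the gradient check fails); heavy smoothing dates it too young — the
same qualitative curve the real chloroplast matrix produces. The
effective/assigned stem rate ratio pins the mechanism:

```python
fit = pc.fit_pl(phylogram, bundle.calibrations, 1e6, bundle.L, seed=1)
print(round(pc.effective_rate_ratio(phylogram, fit, pc.INGROUP_TAXA), 3))
# 0.002  -- the stem branch is ~500x shorter than the clock rate predicts
```

## Command line

`plchron` exposes `date`, `pergene`, `subsample`, `simulate`, `diagnose`,
`ortho-filter` and `aln-stats` subcommands over YAML configs; every run is
deterministic given `--seed` and writes TSV tables stamped with a config
hash. `plchron simulate --scenario chloroplast-like --with-alignment`
writes a complete synthetic dating problem plus a ready-to-run config.

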