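# discosca

Common and distinctive component analysis of linked omics data blocks.

## The problem

Systems-biology studies routinely measure the *same* set of entities with
several instruments, or under the same conditions in several organisms:
metabolite peak tables for one set of *E. coli* cultures from both GC-MS
and LC-MS, or expression of orthologous genes over aligned cell-cycle
states in yeast and human.  The result is two (or more) data blocks
**X**₁ (I₁ × J) and **X**₂ (I₂ × J) sharing their column mode.  The
scientific questions are: which latent processes underlie the joint data,
and which of those are **common** to all blocks versus **distinctive** for
one of them (present in one platform or organism, absent elsewhere)?

`discosca` implements the two fully simultaneous approaches to this
decomposition, their model-selection diagnostics, a generator for
benchmark data with known common/distinctive structure, and recovery
metrics.

## Methods in brief

**Generalized SVD (GSVD).**  A joint factorization

```
X₁ = U₁ S₁ Vᵀ,   X₂ = U₂ S₂ Vᵀ,
```

with U₁, U₂ column-orthogonal, S₁ = diag(c), S₂ = diag(s) and
c²_q + s²_q = 1, and a shared full-rank V (J × Q),
Q = rank([X₁ᵀ X₂ᵀ]ᵀ).  c²_q is the share of component q's variation
falling in block 1, so c²_q ≈ 0.5 marks a common component and c²_q near
1 (or 0) a distinctive one.  The *naive* GSVD is a full decomposition: its
leading components are **not** a least-squares approximation, and on noisy
data with common structure they can account for strikingly little
variation.  The *adapted* GSVD first replaces the concatenated data by its
rank-R truncated-SVD approximation and then decomposes that, restoring
least-squares optimality.

**DISCO-SCA.**  Simultaneous component analysis (SCA) fits all blocks with
one shared factor P (J × R, orthonormal here) and block-specific factors
T_k via the truncated SVD of the concatenation X_c.  Since (T B, P B) fits
identically for any orthogonal B, the rotation is chosen to reveal
structure: writing W for the binary mask with ones where a distinctive
component should vanish, B minimizes ‖W ∘ (T B)‖²_F over orthogonal B
(iterative majorization with orthogonal-Procrustes updates).  When the
numbers of common/distinctive components are unknown, every assignment is
tried — (R+1)(R+2)/2 of them for two blocks — and scored by the maximal
componentwise deviation from its target (leaked variation for distinctive
components, between-block VAF imbalance for common ones); the least
deviating target is retained.

**Recovery metrics.**  Tucker's congruence φ = aᵀb/(‖a‖‖b‖) between true
and estimated components, after optimal matching over permutations and
reflections.

## Worked example

```python
import numpy as np
from discosca import (paper_condition, simulate_blocks, sca, select_target,
                      gsvd, gsvd_vaf, recovery_report)

# one pair of linked blocks: 2 distinctive components per block + 2 common,
# 20% noise, blocks of 144x28 and 44x28
pair = simulate_blocks(paper_condition("mixed", seed=7))

model = sca(pair.blocks, R=6)                 # simultaneous components
best, table = select_target(model, seed=0)    # try all 28 targets
print("selected target:", best.target.label())
print("max deviation:  %.3f" % best.deviations.max_deviation)
print("DISCO block totals: X1=%.2f X2=%.2f" % tuple(best.rotated.vaf.block_totals))

naive = gsvd_vaf(gsvd(pair.blocks), pair.blocks)
print("naive GSVD totals (top 6): X1=%.2f X2=%.2f"
      % tuple(naive.per_component_per_block[:6].sum(axis=0)))

rep = recovery_report({"V": pair.truth["V"]}, {"V": best.rotated.shared_factor})
print("congruence with true V: %.3f" % rep["V"])
```

prints

```
selected target: d1=2,d2=2,common=2
max deviation:  0.009
DISCO block totals: X1=0.84 X2=0.86
naive GSVD totals (top 6): X1=0.41 X2=0.47
congruence with true V: 0.989
```

Target selection recovers the generating structure (two distinctive
components per block, two common) with a near-zero deviation.  The six
DISCO components account for 84–86% of each block — the 20% noise floor —
while the six best naive-GSVD components explain only 41%/47%: the full
decomposition smears common structure over many weakly fitting components.
The rotated shared factor is congruent with the generating one at
φ = 0.989.

## Command line

Every step is also a subcommand of the `discosca` executable, reading and
writing TSV matrices (header row = shared column ids, first column = row
ids) plus a JSON run summary:

```sh
discosca simulate --condition mixed --seed 7 --out-dir sim
discosca scree sim/X1.tsv sim/X2.tsv --rank 10 --out-dir scree
discosca disco sim/X1.tsv sim/X2.tsv --rank 6 --select-target --out-dir out
discosca gsvd sim/X1.tsv sim/X2.tsv --out-dir out_gsvd
discosca evaluate sim/truth.json out/shared_factor.tsv --out-dir eval
```

`discosca preprocess` applies the usual chain for omics blocks
(below-detection imputation by half the smallest detected value, square
root transform, per-row centering and scaling to unit sum of squares,
block weighting).  All randomness flows from `--seed`; identical
invocations produce byte-identical outputs.

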