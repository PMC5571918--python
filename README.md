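# phyquart

Quartet tree evaluation that combines Hennigian site-pattern polarization
with maximum-likelihood estimation of expected convergent site-patterns —
a method for choosing among the three possible unrooted trees of four taxa
(or four user-defined clans) that stays reliable under the extreme
branch-length asymmetries where plain maximum-likelihood topology selection
is misled by long-branch attraction (LBA).

It is aimed at phylogeneticists working with large nucleotide alignments
(phylogenomic supermatrices, RADseq-scale data) who want an independent,
signal-dissecting check on quartet relationships: when this score and ML
agree, LBA is an unlikely explanation of the ML tree; when they conflict,
the ML resolution deserves suspicion.

## The method

For four aligned sequences with roles A, B, C, D there are three unrooted
topologies, `q1 = AB|CD`, `q2 = AC|BD`, `q3 = AD|BC`.  Every alignment
column falls into one of 15 structural site-pattern classes; the
split-supporting ones are the symmetric `{XXYY}` and asymmetric
`{XXYZ}`/`{YZXX}` shapes, and the four singleton classes (`{YXXX}`, …) act
as a proxy for terminal branch lengths.  For each topology *x* and each of
its two polarities *z* (which half of the split carries the derived state):

- `tau_x` — observed split support (symmetric + both asymmetric classes);
- `rho_z` — the asymmetric patterns whose sharing is on the *ancestral*
  side: plesiomorphic, removed from the support;
- `kappa_z` — the expected number of convergent split-supporting patterns:
  the mean, over GTR+Γ+I maximum-likelihood fits of the two *alternative*
  topologies, of the expected symmetric + derived-side asymmetric counts at
  the alignment length (if these patterns would arise anyway under the rival
  trees, they are chance similarity, not synapomorphy);
- correction factors `omega_obs = 1 − 4·phi/N` (phi = smallest, N = total
  singleton count; observed) and `omega_exp` (same functional form on the
  expected singleton counts of the two alternative fits, averaged), which
  damp support in proportion to branch-length asymmetry;
- the score
  `theta_z = S_obs·(1 − omega_obs) − kappa_z·(1 − omega_exp)`
  with `S_obs = tau − rho_z` (the package also implements the variant that
  multiplies by `omega` instead of its complement; see
  `docs/methods.md` for why the complement form is the default);
- per topology, `delta_x = max(theta_right, theta_left)`; finally the
  normalized weights `lambda_x = (delta_x − delta_min) / Σ(delta − delta_min)`,
  which sum to 1.  The winning topology is the one with the largest weight.

Exactly three constrained GTR+Γ+I fits are performed per quartet (one per
topology); each fit serves as the "alternative model" for the other two
topologies.  Likelihoods are computed exactly on the 256-pattern spectrum,
so 250 kbp alignments cost the same as 1 kbp ones.

The package also ships the quartet sequence simulator (GTR + continuous-Γ
rates + invariant sites on Farris/Felsenstein/one-long/three-long
branch-length designs), a plain-ML baseline, and a grid runner for
head-to-head reconstruction-success experiments.

## Worked example

Simulate a classic Felsenstein-zone quartet — two long (1.5) non-adjacent
terminal branches, two short (0.1), internal branch 0.01, GTR with
continuous Γ (α = 1) and 30% invariant sites, 250 kbp — and score it:

```python
from phyquart.simulate import SimulationConfig, simulate_alignment, study_model
from phyquart.scoring import evaluate_quartet
from phyquart.mltree import ml_quartet
from phyquart.patterns import tally

cfg = SimulationConfig("felsenstein", bl1=0.01, bl2=1.5, L=250_000,
                       model=study_model(1.0), seed=42)
qa = simulate_alignment(cfg)          # true topology: q1 = AB|CD

t = tally(qa)
print({x: t.tau(x) for x in ("q1", "q2", "q3")})
# {'q1': 8521, 'q2': 38858, 'q3': 8563}

scores = evaluate_quartet(qa)
print({k: round(v, 3) for k, v in scores.lam.items()}, scores.winner)
# {'q1': 0.529, 'q2': 0.0, 'q3': 0.471} q1

ml = ml_quartet(t, fixed_alpha=1.0, fixed_p_inv=0.3)
print(ml.winner)
# q2
```

The raw split support `tau` is dominated by `q2` (38 858 columns pair the
two long branches A and C — almost all of it convergence), and plain ML is
attracted to the same wrong tree.  The polarized score subtracts the
ML-expected convergence and hands the largest weight to the true topology
`q1`, with `q2` zeroed out.

The same analysis from the shell:

```bash
phyquart score-alignment --aln lba.fasta --out report.tsv
```

writes one tab-separated line per quartet: the four taxon labels, the three
`lambda` weights, the six polarized `theta` scores, `omega_obs` and the
number of sites used after gap/ambiguity exclusion.  Alignments with more
than four taxa need a clan file (`--clans`, four lines
`name: tax1,tax2,...`); one taxon is drawn from each clan per quartet.
Simulation grids run from a YAML config via `phyquart simulate-grid`.

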