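# rrspace

Representative random sampling of chemical space: enumerate every feasible
sum formula of a valence-constrained chemical space, estimate how many
distinct molecular graphs each formula admits *without* enumerating them,
draw approximately uniform random molecules across the whole space, and
score how representative an existing molecule database is of its underlying
space.

Chemical spaces grow far too fast for systematic enumeration, so databases
built from enumerable subsets carry structural bias that propagates into any
statistics computed from them. `rrspace` is for researchers who need
unbiased samples from a molecular graph space — for benchmarking, training
set design, or characterizing the space itself — and for auditing existing
databases against the space they claim to cover.

## The method in brief

A space is a set of atom types (element, valence) with an atom-count range.
Sampling is two-level:

1. **Formulas.** All constitutions are found by nested integer partitions
   over valence types and then elements, keeping only degree multisets
   realizable as connected loop-free multigraphs.
2. **Counts.** For each labeled degree sequence *d*, the number of
   protomolecules |U(d)| is obtained from the best available tier:
   exact enumeration (small *d*); the small-world relation
   ln |U(d)| ≈ 1.220 · l_G − 0.7295, where l_G is the mean pairwise graph
   edit distance of randomly sampled protomolecules; the nonpure reduction
   N_P(d) = ∏_v ∏_i C(Σ_{j≥i} c_j, c_i) with
   l_G(d) = (1 + ln N_P / Σ d_i) · l_G(d_U); or the calibrated asymptotic
   multigraph count with a t! saturation correction.
3. **Molecules.** A stoichiometry is drawn proportionally to its count and
   a protomolecule is sampled by a double-edge-swap MCMC whose stationary
   law is made uniform over isomorphism classes via an automorphism-order
   Metropolis factor. Element labels are attached uniformly afterwards.

Database representativeness is scored by the Kolmogorov–Smirnov statistic
and the Kullback–Leibler divergence between the size-ordered stoichiometry
CDFs of the space and of the database.

See `docs/methods.md` for assumptions, parameter conventions and limits.

## Worked example

Define a space of tetravalent carbon and monovalent hydrogen with 2–6
atoms, then enumerate, count, sample and audit it:

```bash
cat > space.yaml <<EOF
C: 4
H: 1
natoms: [2, 6]
EOF

rrs enumerate --space space.yaml --out formulas.csv
# 11 formulas -> formulas.csv

rrs count --space space.yaml --db counts.csv --seed 1
# 11 new records -> counts.csv (11 total)

rrs sample --space space.yaml --n 20 --seed 7 --out samples.smi --db counts.csv
# 20 molecules -> samples.smi

rrs compare --space space.yaml --db samples.smi --counts counts.csv \
    --fractions 0.5,1.0 --seed 7 --out report.csv
# KS=0.1558 KL=0.3455 (eps-floored bins: 6; skipped records: 0) -> report.csv
```

`formulas.csv` lists each formula with its degree-sequence key; `counts.csv`
records one count per degree sequence with its tier (all `exact` here, since
every formula is within the enumeration cap). The sampled SMILES include
exotic but valence-valid topologies (`C1=C=C=C=C=C=1`,
`[H]C1=C=C1[H]`, ...): the sampler covers molecular *topologies*, with no
stability filtering. The KS of 0.16 against a 20-molecule sample reflects
small-sample noise — the subsample report shows it shrinking as the sample
grows.

The same operations are available as a library:

```python
from rrspace import make_space, sample_space, SamplerConfig

space = make_space({"C": 4, "H": 1, "natoms": [2, 6]})
samples = sample_space(space, 100, config=SamplerConfig(seed=7))
```

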