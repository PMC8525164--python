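# hostphylo

Phylogenetic analysis of insect–host-plant associations, built around the
kind of question asked of herbivore–host systems such as Dacini fruit
flies: is host breadth phylogenetically conserved, does the chance that two
plants share a herbivore decay with the plants' phylogenetic distance, and
which host families were ancestral?

The package is aimed at researchers with (a) a herbivore phylogeny, (b) a
host-plant phylogeny with branch lengths in Myr, and (c) a curated
association table (fly species, host species, host genus, host family). It
provides:

- **Host-breadth profiling and polyphagy partitions** — distinct host
  species/genera/families per fly; binary "feeds on more than *t* families"
  traits.
- **Phylogenetic signal** — Blomberg's *K* with a randomisation test
  (p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm)) and Pagel's *λ* by ML on
  [0, 1] with a one-sided LRT, for continuous and 0/1 characters, where

      K = (MSE0/MSE) / E[MSE0/MSE | Brownian motion],

  with MSE0 the ordinary and MSE the phylogenetically (GLS-)corrected mean
  squared error under the tree covariance **V**.
- **Host-sharing regression** — for each fly, a random *source* host genus;
  logistic regression of "target genus attacked" on
  x = log10(patristic distance + 1), pooled over flies, repeated over many
  source draws: logit S = β₀ + β₁·x, with percentile intervals over runs.
- **DEC\*** — dispersal–extinction–cladogenesis on host-family ranges with
  the null range disallowed: ML rates (d, e), and marginal ancestral-range
  probabilities at every node of a strict-clock chronogram.
- **Synthetic data generators** for all of the above with known ground
  truth, plus an end-to-end, config-driven pipeline CLI.

## Worked example

Simulate a study-shaped system (37 flies, 286 host genera, 87 families,
with 8 monophages and 11 extreme polyphages) and run every stage:

```bash
hostphylo simulate --preset dacini-like --seed 1 --outdir demo
hostphylo sharing --matrix demo/matrix.tsv --host-tree demo/host_tree.nwk \
    --runs 1000 --seed 1 --outdir demo/sharing
```

or in Python:

```python
from hostphylo.synthetic import simulate_association_system
from hostphylo.associations import host_breadth, filter_for_dec
from hostphylo.host_sharing import resample_regression
from hostphylo.trees import patristic_distances

system = simulate_association_system(
    seed=1,
    breadth_profile={"n_monophages": 8, "n_extreme_polyphages": 11,
                     "extreme_min_families": 20},
)
profile = host_breadth(system.table)
print((profile.n_host_families == 1).sum(), "monophages of", len(profile))
# -> 8 monophages of 37

fit = resample_regression(system.matrix,
                          patristic_distances(system.host_tree),
                          n_runs=1000, seed=2)
print(f"logit(S) = {fit.beta0_mean:.4f} + {fit.beta1_mean:.4f} * log10(d+1)")
# -> logit(S) = -0.7497 + -0.6660 * log10(d+1)
```

The first block reproduces the bookkeeping of the emulated study system:
8/37 flies (21.62%) are restricted to one host family, 11/37 (29.73%) use
twenty or more, and dropping the extreme polyphages plus one designated
oligophage leaves 25 species for the DEC* reconstruction. The fitted
equation gives the probability that a host at distance d (Myr) shares a
fly with the source host, Prob = exp(logit S)/(1 + exp(logit S)),
decreasing in d when β₁ < 0; on this narrow-span 300-Myr host tree the
randomized-source design recovers a damped slope (see
`docs/methods.md` for the calibration geometry where the slope is
recovered to within ±0.2).

The end-to-end pipeline is driven by a YAML config:

```bash
hostphylo run --config run.yaml     # stages: breadth, signal, sharing,
                                    # chronogram, dec; MANIFEST.json
                                    # records completeness and seeds
```

## Layout

- `src/hostphylo/trees.py` — Newick I/O, patristic/covariance matrices,
  strict-clock chronogram, polytomy resolution
- `src/hostphylo/associations.py` — association tables, breadth,
  partitions, interaction matrices, DEC filters
- `src/hostphylo/phylosignal.py` — Blomberg's K, Pagel's λ, tests
- `src/hostphylo/host_sharing.py` — randomized source-host logistic
  regression
- `src/hostphylo/dec.py` — DEC* state space, likelihood, ML rates,
  ancestral marginals
- `src/hostphylo/synthetic.py` — generators with serialized ground truth
- `src/hostphylo/pipeline.py`, `cli.py` — orchestration and the
  `hostphylo` command
- `docs/methods.md` — models, assumptions, calibration design, limitations
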