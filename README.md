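# ppimod

Module-aware protein–protein interaction (PPI) prediction from annotated
networks.

`ppimod` fits a Bayesian generative model of an undirected PPI network whose
proteins carry flat categorical annotations (e.g., Gene Ontology terms keyed
by aspect). The model assumes K latent functional modules: module proportions
have a Dirichlet prior, each protein draws a module label, annotations are
drawn in two stages (category, then value, from module-specific
multinomials), and edges follow a stochastic block model with Beta priors on
the block probabilities. Mean-field variational inference yields a
row-stochastic membership matrix; candidate pairs are then scored by summing
membership-weighted, length-penalized simple paths between them, and raw
scores are calibrated into probabilities by the fraction of known
interactions in a sliding rank window. An evaluation harness provides
five-fold cross-validation with constrained negative sampling against a
degree-normalized length-3-path (L3) baseline.

## Layout

| module | role |
| --- | --- |
| `ppimod.netio` | annotated-network data model, edge-list/TSV/GAF I/O, network statistics |
| `ppimod.generate` | generative model and simulator (ground-truth networks for testing) |
| `ppimod.infer` | variational inference of the membership matrix (ELBO-monotone CAVI) |
| `ppimod.score` | simple-path enumeration, weight/decay scoring, brute-force oracle |
| `ppimod.predict` | ranked scoreboard and sliding-window probability calibration |
| `ppimod.evaluate` | L3 baseline, negative sampling, metrics, cross-validation, K sweep |
| `ppimod.cli` | `ppimod` command-line front end |

## CLI

All subcommands are reproducible under `--seed`; logging goes to stderr and
results to files under `--out-dir`. A YAML config (`--config`, one section
per subcommand) supplies defaults that flags override.

```sh
# simulate a 3-module network with ground truth
ppimod simulate --k 3 --n 300 --categories 3 --domain-size 6 --seed 1 --out-dir run/

# descriptive statistics
ppimod stats --edges run/edges.tsv --out-dir run/

# infer the membership matrix
ppimod fit --edges run/edges.tsv --annotations run/annotations.tsv \
    --k 3 --seed 1 --out-dir run/

# calibrated probabilities for candidate pairs
ppimod predict --edges run/edges.tsv --membership run/membership.tsv \
    --pairs pairs.tsv --phi 1.0 --max-interior 3 --half-width 50 --out-dir run/

# five-fold cross-validated evaluation, and a K sweep with shared folds
ppimod evaluate --edges run/edges.tsv --annotations run/annotations.tsv \
    --k 3 --seed 1 --out-dir run/
ppimod sweep-k --edges run/edges.tsv --annotations run/annotations.tsv \
    --k-min 2 --k-max 20 --seed 1 --out-dir run/
```

File formats: edge lists are two whitespace-separated identifiers per line
(`#` comments ignored); annotation tables are TSV with a
`protein\tcategory\tvalue` header; GAF 2.x is accepted with `--gaf` (aspect
P/F/C becomes the category). Membership matrices are TSV with a
`protein\tmodule_1..module_K` header.

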