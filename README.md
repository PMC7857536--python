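# protstab

Protein degradation kinetics and stability classification from
pulsed-SILAC time courses.

In a pulsed-SILAC experiment on exponentially dividing cells (e.g.
*E. coli* at a ~60-min generation time), the pre-switch isotope's M/L
intensity ratio of every protein decays for two reasons: dilution by
cell division at rate λ_dil = ln2/t_cc, and proteolysis at rate λ_deg.
`protstab` turns per-protein ratio time series into degradation rates
and stability classes, and asks what sequence and network properties
distinguish unstable proteins:

1. **Kinetics** — fit each protein's normalized trajectory with the
   nested models y(t) = A·e^(−t·λ_dil) + B (dilution only) and
   y(t) = A·e^(−t(λ_dil+λ_deg)) + B, decide between them with a
   likelihood-ratio test (BH-corrected), and convert rates to
   half-lives t½ = ln2/λ_deg.
2. **Mixture** — split the degradable fraction into slow- and
   fast-degrading classes with a two-component Gaussian mixture on log₂
   half-lives (EM, parametric-bootstrap model selection, posterior-0.5
   assignment, right-tail reassignment of pseudo-fast outliers).
3. **Features** — build a 188-column per-protein table: intrinsic
   disorder summaries, interaction-network context, a 128-dimensional
   random-walk node embedding, Biopython physicochemistry (raw and
   connectivity-normalized), N-end-rule position-2 encodings, and five
   ClpXP-style terminal degron motifs.
4. **Classification** — LASSO logistic regression over seven task
   setups (pairwise, one-vs-rest, three-class) with 10×10-fold
   stratified cross-validation, nested penalty selection, a label
   permutation null, and significance testing.
5. **Simulation** — a ground-truth-labeled synthetic cohort generator
   (trajectories, sequences, disorder, network) so the entire pipeline
   is testable end to end without any external data.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Simulate a cohort, fit kinetics, split the degradable set, extract
features and compare groups — from the shell:

```sh
protstab simulate --seed 3 --out sim/
protstab fit --trajectories sim/trajectories.tsv --out calls.tsv
protstab mixture --calls calls.tsv --n-boot 100 --out labels.tsv --report mix.json
protstab features --fasta sim/sequences.fasta --edges sim/edges.tsv \
    --disorder sim/disorder.tsv --labels labels.tsv --out features.tsv
protstab stats --features features.tsv --out stats.tsv
```

or from Python:

```python
import numpy as np
import protstab as ps

cfg = ps.SimulationConfig(n_stable=300, n_slow=120, n_fast=40, seed=1)
cohort = ps.generate_cohort(cfg)

series = [ps.normalize_series(s) for s in cohort.series_list()]
kept, discarded = ps.filter_series(series)
calls = ps.call_stability(kept)
print(calls["status"].value_counts().to_dict())

deg = calls[calls.status == "degradable"]
table, fit, boot = ps.classify_half_lives(
    deg.half_life_min.to_numpy(), protein_ids=deg.protein_id, seed=1
)
print(np.round(fit.means, 2), np.round(fit.weights, 2))
```

On this cohort (300 truly stable, 160 truly degradable proteins; 8
trajectories filtered before fitting) the fit/call step prints

```
{'stable': 286, 'degradable': 166}
```

— most truly degradable proteins are recovered, while a handful of
stable proteins cross the q < 0.05 line because the small-sample LRT is
somewhat anti-conservative at six time points (see
`docs/methods.md`). The mixture step prints

```
[7.47 6.95] [0.64 0.36]
```

the component means on the log₂-minute scale and their weights. The
slow mean (2^7.47 ≈ 177 min) sits close to the generative 200 min; the
fast mean lands above the generative 48 min on this cohort because the
input to the mixture is *estimated* half-lives — estimation error on
slow proteins spreads their log₂ values downward, and with 166
observations the two components overlap. On the true half-lives, or at
larger cohort sizes, the recovered means tighten (the recovery numbers
that `scripts/acceptance.py` reports are computed on a clean n = 400
mixture draw).

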