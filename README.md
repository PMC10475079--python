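# lrcausal

Ligand–receptor (LR) communication inference from pseudotime-ordered
single-cell expression data.

Most cell–cell communication tools score LR pairs by co-expression at a
single snapshot. During development, signaling is a *process*: a ligand is
induced, its receptor responds in a partner cell, transcription factors (TFs)
downstream reshape the program that feeds back on the ligand. `lrcausal`
treats the ordered cells of a trajectory as a time series and asks, for every
LR pair, whether its communication activity *temporally precedes* (or follows,
or mutually couples with) the activity of temporal TF programs — the classic
Fgf4–Fgfr2 ↔ Gata6 loop of the mouse blastocyst being the motivating example.

## The model

For cells ordered by stage and pseudotime, the **interaction score** of a pair
within one lineage (autocrine) is the per-cell geometric mean

&nbsp;&nbsp;&nbsp;&nbsp;IS_t = √(e_t,ligand · e_t,receptor),

and across two lineages (paracrine) the product of the lineage-level ligand
and receptor signals. The workflow is:

1. **Screen** — keep pairs whose ligand and receptor co-vary along the
   ordering (|PCC| > 0.1 autocrine; Spearman > 0.2 on interpolated grids,
   paracrine). The 0.1 default can be re-derived on any dataset by the
   double-tangent construction on the ranked-correlation curve
   (`derive_cutoff`).
2. **Temporal TFs** — build per-TF co-expression regulons, call TFs whose
   regulons are enriched (hypergeometric, BH-adjusted) for trajectory-variable
   genes, and Ward-cluster them into k = 6 groups with mean-profile activity
   series.
3. **Granger classification** — for each surviving pair, test both directions
   between IS_t and each cluster activity with the bivariate Granger F test
   (lag 1, nested OLS: y_t ~ 1 + y_{t−1..t−L} [+ x_{t−1..t−L}], α = 0.01),
   taking the minimum p over clusters per direction. Pairs are labelled
   **forward** (LR→TF), **backward** (TF→LR), **feedback** (both), or none.
4. **Paracrine extension** — unequal-length lineages are aligned by
   Gaussian-kernel interpolation (bandwidth `winsz = 0.1`, 200 grid points);
   receiver master TFs are Granger-linked to each pair and the
   highest-|SCC| link (**SCC_ens**) calls a pair *active* when |SCC_ens| > 0.8.

Validation statistics (gene-set enrichment ratios with hypergeometric tails,
transcription-inhibition deltas with two-round hierarchical clustering, and a
one-sided Welch test between pair groups) are included, as is a synthetic-data
module that plants known causal structure for every one of these steps.

## Worked example

```bash
python examples/autocrine_workflow.py
```

simulates 200 stage-labelled cells (500 genes, 60 LR pairs of which 8 carry
planted forward/backward/feedback coupling to TF clusters) and runs the full
autocrine pipeline:

```
15 pairs passed the |PCC| > 0.1 co-variation screen
  Lg000-Rc000: planted feedback  called feedback  [hit]
  Lg001-Rc001: planted backward  called backward  [hit]
  ...
class recall on planted pairs: 6/8
```

A `feedback` call means both Granger directions between the pair's
interaction score and some tTF-cluster activity are significant at α = 0.01 —
the signature of a self-reinforcing signaling loop. The other examples cover
the paracrine two-lineage workflow (`paracrine_workflow.py`, planted motif
recovered with SCC_ens = 0.923), Granger calibration/power
(`granger_calibration.py`: type-I error 0.008 at α = 0.01; 100/100 power at
coupling 0.8), cutoff derivation, interpolation sensitivity, and the
validation statistics.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic datasets from the given seed, runs both the
autocrine and the paracrine pipeline end to end, prints a one-line summary of
each, and writes the results JSON to `--out`.

## Repository layout

```
src/lrcausal/     io, ordering, covary, regulon, granger, validate,
                  synthetic, pipeline
examples/         one narrative script per capability
tests/            pytest suite (unit + property + acceptance)
docs/methods.md   models, parameters, design choices, known limitations
```
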