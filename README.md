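# poolscreen

Design, simulate and bench-script **sample pooling (group testing)
strategies** for pathogen screening.

When a pathogen is rare, testing every specimen individually wastes most
assays on negatives. Group testing pools specimens and tests the pools: a
negative pool clears all of its members at once, a positive pool is
resolved by further testing. `poolscreen` implements six classical and
practical pooling strategies under a noiseless binary assay (a pool is
positive iff it contains at least one positive sample) and measures the
costs a screening lab actually cares about:

- **T** — number of tests (reagents, cost),
- **S** — number of sequential steps (turnaround time),
- **max pool size** — samples per pool (limit-of-detection risk),
- **P** — pipetting actions per pipette channel count *c* (complexity,
  human-error risk),
- **robustness** — extra tests/steps when the expected number of positives
  k̂ misestimates the true *k*.

## Strategies

| strategy | type | idea |
|---|---|---|
| `sudoku` | non-adaptive | CRT window pooling: sample *s* joins pool *s* mod *Wᵢ* for *w* pairwise co-prime windows *Wᵢ* > √N; up to *w−1* positives decode in one step with T = ΣWᵢ |
| `grid2d` | non-adaptive | samples arranged in M square D×D grids; every row and column pooled (T = 2DM); positives at intersections of positive rows/columns |
| `s_stage` | multi-stage | Li's S-Stage: S = ⌈ln(N/k̂)⌉ stages with pool sizes nᵢ = ⌈(N/k̂)^((S−i)/S)⌉; survivors of positive pools re-pooled collectively |
| `modified3` | multi-stage | S-Stage capped at 3 steps; each positive pool is recursively subdivided in place (multichannel-pipette friendly) |
| `halving` | adaptive | Binary Splitting by Halving: pool everything, binary-search one positive at a time; needs no k̂; tests = steps |
| `gbs` | adaptive | Hwang's Generalized Binary Splitting: initial group 2^α, α = ⌊log₂((N−k̂+1)/k̂)⌋, recomputed as positives are found; near-optimal test count |

Both non-adaptive designs resolve ambiguous decodes with a single second
round of individual retests, so every strategy always recovers the exact
positive set.

## Worked example

Screen one 96-well plate expecting about two positives (k̂ = 2) with the
Modified 3-Stage scheme:

```python
import poolscreen as ps

sv = ps.place_positives(96, 2, seed=11)      # ground truth: wells 12 and 95
out = ps.run_modified_3stage(sv, k_hat=2)
print(out.tests, out.steps, out.max_pool_size, out.pipettings)
# 22 3 16 {1: 136, 8: 28, 16: 22}
```

The design is 6 first-stage pools of 16 samples, positive pools split into
4 subgroups of 4, then individual tests — here 6 + 8 + 8 = 22 tests in 3
steps instead of 96 individual tests, with no pool larger than 16 and only
28 draws with an 8-channel pipette. `out.decoded_positives` equals the true
positive set.

The same design as a bench protocol (pools are contiguous column pairs of
the plate, drawn with an 8-channel pipette):

```
$ poolscreen protocol --k-hat 2
Stage 1 / pool S1-P0: combine A1, B1, ..., H2 into D0-A1 (8-channel)
...
$ poolscreen replay-validation
 plate  k  k_hat  N positive_wells  tests  pipettings_8ch  decoded_wells  recovered
     1  3      2 96   (F1, A4, G9)     30              36   (A4, F1, G9)       True
     2  1      2 96          (H2,)     14              20          (H2,)       True
...
Total tests: 120  Total pipettings (8-channel): 168
```

`replay-validation` replays a wet-lab spike-in experiment: eight 96-well
plates of milk-microbiome background with ten *C. burnetii*-spiked wells
were screened in 120 assays (~84% fewer than 768 individual tests), and
every spiked well was recovered.

Monte-Carlo comparisons and misestimation sweeps:

```
$ poolscreen simulate --strategy all --n 96 --k 1..20 --k-hat match \
      --grid-dim 10 --replicates 100 --seed 7 --out-dir out/
$ poolscreen tables --which tests          # mean ± sd test counts per cell
```

## Layout

- `poolscreen.core` — status vectors, pools, outcome records, pooled-test
  primitive, partition/pipetting arithmetic
- `poolscreen.nonadaptive` — window (CRT) pooling and 2D grids: design,
  decode, retest
- `poolscreen.staged` — S-Stage and Modified 3-Stage
- `poolscreen.splitting` — Halving and Generalized Binary Splitting
- `poolscreen.simulate` — replicate driver, summaries, robustness sweeps,
  min-max normalisation, CSV/JSON writers
- `poolscreen.plate` — 96-well addressing, interactive protocol sessions,
  validation replay
- `poolscreen.cli` — `poolscreen` command

See `docs/methods.md` for the models, formulas, integer conventions and
known limitations.
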