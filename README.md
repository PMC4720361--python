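# firereserve

Reserve site selection under spatially-correlated (spreading-fire)
disturbance risk.

The package selects reserve networks that maximize the *expected number of
species surviving* a stochastic habitat disturbance, and compares two risk
scenarios on the same landscape:

* **correlated risk** — a fire ignites in one uniformly random parcel and
  spreads to its contiguous neighbours (first-order queen contiguity on
  square grids, the six edge neighbours on hexagons);
* **independent risk** — a risk-equalized null that burns the *same
  distribution of parcel counts* but scatters the burned parcels uniformly
  at random, isolating the effect of spatial pattern from total risk.

Small instances are solved exactly (full enumeration of burn patterns and
candidate reserves, with a closed-form hypergeometric representation of the
independent model); large hexagonal landscapes are solved with simulated
annealing (Metropolis acceptance, geometric cooling, best-so-far tracking).

## Layout

| module                   | contents |
|--------------------------|----------|
| `firereserve.landscape`  | square focal grids with buffer rings, hexagonal lattices, queen/edge adjacency, shared-border counts |
| `firereserve.burn`       | burn-pattern enumeration, Monte-Carlo fire sampling, size-matched independent nulls, closed-form independent model |
| `firereserve.coverage`   | reserve evaluation (expected species, outcome distribution, per-species survival), exact optimizer, dispersion metrics |
| `firereserve.anneal`     | simulated-annealing solver with incremental evaluation and optional per-step fire resampling |
| `firereserve.synthetic`  | random stylized species layouts, hotspot classification, Oregon-like hex species matrices, the stylized Monte-Carlo experiment |
| `firereserve.io` / `cli` | species-matrix CSV, landscape specs (YAML/JSON), burn-model JSON, `firereserve` command line |

## CLI quick tour

```bash
# a 5x5 focal grid with a one-parcel buffer: 25 focal / 49 ignition parcels
firereserve landscape --type square --rows 5 --cols 5 -o ls.json

# enumerate the 49 correlated burn patterns
firereserve burns enumerate --landscape ls.json -o corr.json

# evaluate a reserve, find all exact optima
firereserve eval  --landscape ls.json --species sp.csv --model corr.json --parcels 7,20
firereserve solve exact --landscape ls.json --species sp.csv --model corr.json --m 2

# large hex landscape: sample fires and anneal a 30-parcel reserve
firereserve landscape --type hex --rows 17 --cols 17 -o hex.json
firereserve synth oregonlike --seed 7 -o oregon.csv
firereserve solve anneal --landscape hex.json --species oregon.csv \
    --m 30 --sims 500 --t0 10 --cooling 0.995 --iters 2000 --seed 1 \
    --trace trace.csv -o result.json

# reference tables for the stylized landscape
firereserve experiment table1
firereserve experiment table2
firereserve experiment stylized --n 100 --m 2 --seed 1 -o records.csv

# one-config pipeline (landscape + species + burn model + one solver)
firereserve run config.yaml
```

Species matrices are CSV: first column the 1-based parcel id, one 0/1
column per species (headerless and whitespace-delimited files are accepted
too).

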