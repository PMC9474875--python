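# tracescape

Analysis of single-nucleus chromatin traces from multiplexed DNA-FISH
imaging (Hi-M and related chromatin-tracing protocols). The input is, per
nucleus, the 3D positions (µm) of a few tens of genomic *barcodes* spanning
one or two topologically associating domains (TADs) — or, equivalently, the
stack of single-nucleus pairwise-distance (snPWD) matrices derived from
them. `tracescape` turns such stacks into:

- **ensemble pairwise-distance maps** — per barcode pair, the first local
  maximum of a Gaussian kernel density estimate of the distance distribution
  (bandwidth 0.25 pixel = 0.0265 µm, distances > 4 µm excluded), a robust
  mode estimator; or the per-entry median;
- **pair correlations** — conformational similarity between two nuclei as
  the Pearson correlation of their vectorized reciprocal distance maps
  (1/d, emphasizing short-range differences), with a shuffled-map null band;
- **locus metrics** — per-nucleus radius of gyration
  Rg² = Σᵢⱼ d²ᵢⱼ / (2N²) computed from distances alone (1 µm outlier mask),
  single-nucleus insulation scores (2×2 window of inverse distances slid
  along the diagonal; lower = more insulated), intra-/inter-TAD median
  distances, the demixing score log₂(intra/inter), inter-TAD contact counts
  (< 250 nm), and Welch's t-test for group comparisons;
- **conformational-space embeddings** — dropout filtering, imputation of
  missing distances from the ensemble map, UMAP embedding
  (n_neighbors = 50, min_dist = 0.1, n_epochs = 500, metric = canberra),
  density-difference cluster boundaries with per-category composition
  percentages, and Leiden partitioning of the embedding's k-NN graph;
- **synthetic cohorts** — a seeded generator of random-coil conformations
  with tunable TAD compaction, border strength, localization error, and
  detection dropout, so the whole pipeline is testable without imaging data.

It is aimed at groups doing sequential DNA-FISH / chromatin tracing who
want a tested, scriptable reference implementation of these statistics.

## Worked example

Generate two synthetic regimes — a plain random coil and a "TAD-on" regime
(per-TAD compaction 0.6, border strength 2) — and compare their border
insulation, ensemble maps and pair correlations:

```python
import numpy as np
from tracescape import SyntheticConfig, generate_cohort, ensemble_map
from tracescape.metrics import insulation_profiles
from tracescape.similarity import pair_correlation_distribution, shuffled_null

coil = SyntheticConfig(n_nuclei=300, regime_label="coil", seed=1)
tad_on = SyntheticConfig(n_nuclei=300, regime_label="tad_on", seed=2,
                         compaction={"TAD1": 0.6, "docTAD": 0.6},
                         border_strength=2.0)
_, stack = generate_cohort([coil, tad_on])

for cohort in ("coil", "tad_on"):
    sub = stack.subset(np.flatnonzero((stack.meta["cohort"] == cohort).to_numpy()))
    med = np.nanmedian(insulation_profiles(sub), axis=0)
    em = ensemble_map(sub, method="kde_mode")
    lib = sub.library
    ia, ib = lib.tad_indices("TAD1"), lib.tad_indices("docTAD")
    pc = pair_correlation_distribution(sub)
    nm, nsd = shuffled_null(sub, seed=7)
    print(cohort, np.nanargmin(med), med[lib.border_index],
          np.nanmean(em.values[np.ix_(ia, ib)]), pc.median_r, nm, nsd)
```

prints (formatted):

```
coil:   IS minimum at position 14 (border = 9), border IS median = 13.57
        ensemble inter-TAD mean = 0.198 um, median pair correlation = 0.297
        (shuffled null -0.000 +/- 0.089)
tad_on: IS minimum at position 9 (border = 9), border IS median = 6.26
        ensemble inter-TAD mean = 0.296 um, median pair correlation = 0.498
        (shuffled null -0.000 +/- 0.088)
```

Read: in the TAD-on regime the population-median insulation profile dips
exactly at the configured border (position 9) and the border score halves,
while in the pure coil the minimum wanders; inter-TAD distances grow with
border strength; and compacted nuclei resemble one another more (median
pair correlation 0.50 vs 0.30), while the shuffled reference stays at zero
in both regimes. Note that even *independent* coil conformations correlate
positively — the reciprocal-distance profile shared by all polymers sees to
that — so the shuffled band, not zero, is the similarity baseline.

## Command line

```sh
tracescape simulate --config regimes.yaml --out stack.h5
tracescape ensemble --stack stack.h5 --method kde_mode --out emap.csv
tracescape paircorr --stack stack.h5 --min-detected 13 --shuffles 10 --seed 7 --out pc.csv
tracescape run --config run.yaml        # full pipeline -> summary.json
```

`tracescape run` executes simulate/ingest → ensemble → pair correlation →
locus metrics → embedding (with density boundaries, composition and Leiden
labels) and writes per-stage CSVs plus a machine-readable `summary.json`.

## Layout

- `tracescape.model` / `tracescape.io` — domain types (barcode library,
  trace collection, PWD stack), validation, CSV/HDF5 readers and writers
  (including a 4DN FOF-CT-style trace-table dialect);
- `tracescape.simulate` — synthetic conformation generator;
- `tracescape.ensemble` — KDE-mode/median ensemble maps, difference maps;
- `tracescape.similarity` — pair correlation and shuffled null;
- `tracescape.metrics` — Rg, insulation, demixing, contacts, Welch tests;
- `tracescape.embedding` — selection, imputation, UMAP, density boundaries,
  composition, Leiden, cluster annotation;
- `tracescape.pipeline` / `tracescape.cli` — configured, seeded runs.

See `docs/methods.md` for the statistical conventions and design choices.
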