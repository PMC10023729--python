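# seerfish

Error-robust barcoding and spatial analysis for **sequential rRNA-FISH**
of microbial communities.

Sequential FISH identifies bacterial taxa by the sequence of fluorophore
colors a cell displays over R imaging rounds: each taxon carries an F-ary,
length-R barcode (F colors, one symbol per round), giving F^R coding
capacity instead of the 2^F − 1 of combinatorial labeling. Because
off-target (non-specific) probe binding corrupts symbols, codebooks are
restricted to codewords with pairwise Hamming distance ≥ 2k, which lets
the decoder correct up to k per-round errors. This package implements the
computational core of that workflow for people designing or simulating
such experiments — entirely on synthetic data:

* **codebook** — greedy construction of maximal minimal-distance barcode
  pools, exact assignment counting (falling factorial), random codebook
  drawing, and an elitist genetic algorithm that optimizes codebooks
  against simulated F1;
* **hybridization** — the binding isotherm
  `E = e^(−ΔG/RT)·Cp / (1 + e^(−ΔG/RT)·Cp)`, probe-candidate filters
  (18–21 nt, 45–60% GC, ≥3 mismatches to non-targets, ΔG < −13 kcal/mol),
  ΔG classing into specific / non-specific / background, and the
  lognormal per-cell intensity model (log10 class means −0.3 / −0.9 / −2,
  σ = 0.3, CCD-normalized);
* **decoding** — t-test symbol calling against background, the lost-cell
  rule (dark in >3 rounds), nearest-neighbor decoding with the 2k
  correction rule, and per-taxon precision / recall / F1;
* **imaging** — a synthetic multi-round microscope (planted ellipse
  cells, PSF blur, noise, per-round drift) and the analysis pipeline:
  cross-correlation registration, adaptive-threshold + watershed
  segmentation, per-cell extraction, end-to-end decoding;
* **spatial** — linear-dipole pair correlation g(r) = P_r/(2 D_i D_j)
  (P_r/D² within a taxon), contact frequency against a random-ellipse
  null, and 10-µm association / differential-association permutation
  tests with Bonferroni correction.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Build an error-robust pool, draw a 12-taxon codebook, simulate cells
under non-specific binding, decode and score:

```python
import numpy as np, pandas as pd
from seerfish import codebook as cb, hybridization as hyb, decoding as dec

pool = cb.generate_pool(F=3, R=8, min_hd=4, seed=1, restarts=100)
print(len(pool), cb.assignment_count(len(pool), 12))
# 60 670295125717176960000        <- ~6.7e20 possible 12-taxon codebooks

book = cb.draw_codebook(pool, S=12, seed=1)

# probe specificity: own taxon specific, two off-target pairs non-specific
taxa = list(book.taxa)
dg = pd.DataFrame(-5.0, index=taxa, columns=taxa)
np.fill_diagonal(dg.values, -14.0)
dg.iloc[0, 1] = dg.iloc[5, 2] = -10.0      # within the (-13.0, -7.3) band
model = hyb.SpecificityModel.from_dg(dg)

report = dec.evaluate_simulation(book, model, n_cells_per_taxon=1000, seed=1)
print(f"precision {report.precision:.3f}  recall {report.recall:.3f}  "
      f"F1 {report.f1:.3f}")
# precision 1.000  recall 0.995  F1 0.997
```

The two non-specific probe pairs occasionally flip a round's symbol, but
the distance-4 code corrects nearly all of them: macro precision/recall
stay above 0.99 where a distance-1 code would misidentify those cells.

The same workflow from the shell:

```sh
seerfish codebook generate --colors 3 --rounds 8 --min-hd 4 \
    --restarts 100 --seed 7 -o pool.csv
seerfish codebook assign --pool pool.csv --taxa taxa.txt --seed 7 -o codebook.csv
seerfish simulate --codebook codebook.csv --dg dg.csv --cells 1000 \
    --seed 7 -o observed.tsv
seerfish decode --codebook codebook.csv --observed observed.tsv -o decoded.tsv
seerfish evaluate --decoded decoded.tsv -o report.json
```

and an end-to-end image pipeline on a synthetic stack:

```sh
seerfish fixtures --scenario syncom12-ideal --seed 5 -o bundle/
seerfish image run --stack bundle/stack --codebook bundle/codebook.csv \
    -o cellmap.csv
# shifts [(0, 0), ...]; identified 48/48 cells -> cellmap.csv
```

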