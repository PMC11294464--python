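# myobarcode

Quantification pipeline for whole-body myofiber turnover in growing
zebrafish imaged with multicolor (Brainbow-style) lineage barcodes.

During post-embryonic growth, zebrafish trunk muscle both adds fast
myofibers (hyperplasia) and enlarges existing ones (hypertrophy), while a
surprising fraction of larval fibers is eliminated and replaced in situ.
Measuring this turnover requires tracking thousands of individual fibers
across weeks in the same animal. Combinatorial fluorophore barcoding makes
that possible: stochastic Cre recombination over ~10 cassette copies gives
each fiber a heritable color, so a fiber can be re-identified across imaging
sessions, and its disappearance — together with the unlabeled newborns
filling its footprint — can be scored as a dissolution–replacement event.

`myobarcode` implements the full measurement chain plus a ground-truthed
synthetic-data generator to validate it:

- **simgen** — stochastic fiber-population simulator (hyperplasia,
  nuclear-domain hypertrophy `V = s·N`, condition-dependent elimination
  hazards, categorical replacement counts, medial-edge spatial bias,
  cassette-draw color barcodes), multichannel cross-section renderer
  (power-diagram tiling, membrane/color/nuclear channels, confocal-style
  noise), and a qPCR Ct-table simulator.
- **quantify** — Gaussian preprocessing (σ = 2), oblique cross-sections,
  watershed fiber segmentation with external-mask import, Laplacian-of-
  Gaussian nucleus detection (diameter 7 µm, MAD-normalized quality ≥ 3),
  nucleus-to-fiber assignment, voxel-count volumes, Otsu labeled-area
  fractions.
- **barcode** — linear-RGB → CIELAB conversion, ΔE (CIE76 default,
  CIEDE2000 optional), agglomerative hue clustering at ΔE = 37.4.
- **tracker** — Hungarian fiber matching (color + space cost), fate
  classification, dissolution-event detection with footprint-based
  replacement assignment, elimination fractions.
- **stats** — percent changes, nuclear-domain OLS fits, weekly reduction
  rates, ΔΔCt fold changes (2^−ΔΔCt), puncta fractions, birth-cluster
  detection (≥5 adjacent newborns), growth summaries.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Track a simulated tagged cohort through two days of fast growth and fit the
nuclear-domain line:

```python
import myobarcode as mb
from myobarcode import tracker, stats

cfg = mb.SimulationConfig(seed=7, n_myotomes=2,
                          initial_fibers_per_myotome=25,
                          t_grid=(14.0, 14.5, 15.0, 15.5, 16.0),
                          growth_condition="FG")
frames, truth = mb.simulate_population(cfg)

tagged = {t: df[df.tagged].reset_index(drop=True) for t, df in frames.items()}
table = tracker.classify_fates(tagged)
print("tagged cohort:", len(tagged[14.0]))
print("eliminated by 16 dpf: %.1f%%"
      % tracker.elimination_fraction(table, 14.0, 16.0))

fit = stats.nuclear_domain_fit(frames[14.0]["volume"],
                               frames[14.0]["nucleus_count"])
print("nuclear-domain slope: %.0f um3/nucleus (R2 = %.2f)"
      % (fit.slope, fit.r_squared))
```

Output:

```
tagged cohort: 50
eliminated by 16 dpf: 46.0%
nuclear-domain slope: 3094 um3/nucleus (R2 = 0.94)
```

The cohort loses 46% of its fibers over two days — consistent with the
fast-growth hazard of ~0.28/day — and the volume-vs-nucleus-count fit
recovers the generating fast-growth 14-dpf unit volume (3.2 × 10³
µm³/nucleus) from 50 noisy fibers.

The same steps are available from the shell:

```sh
myobarcode simulate --seed 7 --out run/ --n-myotomes 2
myobarcode track --table run/fibers.csv --out run/tracks/
myobarcode report --tracks run/tracks/tracks.csv \
    --events run/tracks/events.csv --out run/report.json
```

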