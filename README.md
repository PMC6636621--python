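# stressidx

Yield-based stress tolerance analysis for plant breeding trials.

When a set of genotypes is grown under normal conditions and under an
abiotic stress (drought, salinity, heat, ...), the pair of mean yields per
genotype — Yp without stress, Ys with stress — is the raw material for
selecting tolerant material. `stressidx` computes, for every genotype, the
nine classical tolerance/susceptibility indices together with the percent
relative change, and the downstream analyses breeders use to act on them:
direction-aware rankings with the average sum of ranks (ASR), relative
frequency classes with genotype membership, Pearson and Spearman
association matrices with heat maps, correlation-matrix PCA with biplots,
and Fernandez A–D grouping with a 3D (Yp × Ys × index) plot. Results export
as a multi-sheet xlsx workbook and/or CSVs.

With Ȳp, Ȳs the trial means, the indices are

| id  | formula                        | best value |
|-----|--------------------------------|------------|
| TOL | Yp − Ys                        | minimum |
| MP  | (Yp + Ys)/2                    | maximum |
| GMP | √(Yp·Ys)                       | maximum |
| HM  | 2·Yp·Ys/(Yp + Ys)              | maximum |
| SSI | (1 − Ys/Yp)/(1 − Ȳs/Ȳp)        | minimum |
| STI | Yp·Ys/Ȳp²                      | maximum |
| YI  | Ys/Ȳs                          | maximum |
| YSI | Ys/Yp                          | maximum |
| RSI | (Ys/Yp)/(Ȳs/Ȳp)                | maximum |

plus RC = 100·(Yp − Ys)/Yp. Ranks (1 = most favourable per the direction
above) are aggregated per genotype over Yp, Ys and the nine indices into
the ASR; the lowest ASR marks the genotype that is consistently superior
across all criteria.

## Worked example

```python
import stressidx as sx

trial = sx.TrialTable(
    genotypes=("Alpha", "Beta", "Gamma", "Delta"),
    yp=[62.0, 58.0, 71.0, 49.0],
    ys=[48.0, 52.0, 40.0, 30.0],
    trait_name="shoot dry weight", units="mg/plant",
)
table = sx.compute_indices(trial)
print(table.frame.round(3).to_string())
```

```
            Yp    Ys      RC   TOL    MP     GMP      HM    SSI    STI     YI    YSI    RSI
Genotype
Alpha     62.0  48.0  22.581  14.0  55.0  54.553  54.109  0.774  0.827  1.129  0.774  1.093
Beta      58.0  52.0  10.345   6.0  55.0  54.918  54.836  0.355  0.838  1.224  0.897  1.266
Gamma     71.0  40.0  43.662  31.0  55.5  53.292  51.171  1.497  0.789  0.941  0.563  0.795
Delta     49.0  30.0  38.776  19.0  39.5  38.341  37.215  1.329  0.408  0.706  0.612  0.864
```

Beta retains 90% of its potential yield under stress (YSI = 0.897) and has
the lowest loss indices (TOL = 6, SSI = 0.355): it is the stable entry.
Gamma has the highest potential yield but loses 44% of it (RC = 43.66),
so its SSI > 1 flags above-average susceptibility. Running
`sx.rank_all(table, trial)` and `sx.sort_by_asr(...)` aggregates all
criteria; the `examples/` directory walks through each capability
(`python examples/02_rank_and_select.py` and friends).

## Command line

```bash
stressidx run --input trial.csv --out results --formats workbook,csv,png
stressidx validate --input trial.csv
stressidx fixtures --out demo.csv --n 90 --seed 1
```

The input is a CSV or xlsx with one row per genotype: a label column and
two numeric columns (Yp then Ys), overridable with
`--label-col/--yp-col/--ys-col`. `--skip pca` (etc.) drops stages;
`--asr-columns 9` restricts the ASR to the nine indices.

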