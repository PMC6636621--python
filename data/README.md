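# Reference regression tables (not distributed)

Two regression tests in `tests/test_acceptance.py` reproduce the published
analysis of two wheat screening trials. The raw genotype-level yields are
not redistributable with this package, so the tables must be placed here by
hand before those tests can run; every other test is self-contained.

Expected files, both plain CSV with a header row and one row per genotype
(label, yield under non-stressed conditions, yield under stressed
conditions, dot decimal separator):

- `dataset1_salinity_90.csv` — 90 wheat genotypes labelled `G1` … `G90`,
  shoot dry weight (mg/plant) under control (`Yp`) and saline (`Ys`)
  conditions.

  ```
  Genotype,Yp,Ys
  G1,...,...
  ```

- `dataset2_water_9.csv` — 9 wheat species under well-watered (`Yp`) and
  water-deficit (`Ys`) conditions, labelled `T. aestivum`, `T. durum`,
  `T. urartu`, `T. boeoticum`, `Ae. tauschii`, `Ae. neglecta`,
  `Ae. triuncialis`, `Ae. crassa`, `Ae. caudata`.

Any column naming works if you adapt the tests' `read_trial_table` call
with an explicit column mapping; the defaults above need none.
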