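# algafp

MALDI-TOF MS fingerprinting of microalgae, as a reusable analysis
pipeline:

- **io_formats** — profile spectra (mzML or two-column xy text), TSV peak
  tables, aligned FASTA, Newick; all readers validate, all writer/reader
  pairs round-trip.
- **preprocess** — Savitzky-Golay smoothing, top-hat (morphological
  opening) baseline subtraction, robust (MAD) noise estimation,
  calibrant-based mass-axis recalibration, and the per-burst quality gate
  (base-peak S:N ≥ 2, intensity ≥ 100, width ≤ 10 m/z, ≤ 500 peaks; all
  inclusive).
- **peaks** — centroided peak detection with S:N thresholding, ±2 m/z
  greedy peak matching, all-replicate consensus peak lists, composite
  (summary) spectra with a 65% mutual-similarity inclusion rule, and
  per-spectrum summary statistics.
- **fingerprint_clustering** — Pearson similarity of binned profiles,
  UPGMA dendrograms (ultrametric, deterministic tie-breaking), pseudo-gel
  rendering.
- **mixtures** — classification of every peak across constituent and
  mixed-culture spectra as constituent-derived-and-observed (M),
  constituent-derived-but-suppressed (P), or mixture-specific (S), plus a
  per-constituent ion-suppression report. A worked example dataset ships
  with the package (`algafp.mixtures.load_packaged_mixture_example`).
- **phylo** — pairwise substitution counts, Kimura two-parameter distances
  with an additive per-gap-column penalty (default 0.12), neighbor-joining
  trees, and tree-congruence reports (per-class monophyly +
  Robinson-Foulds) against an MS dendrogram.
- **synthetic_data** — seeded generators for strain templates, replicate
  spectra (Gaussian peaks + drifting baseline + noise + mass jitter),
  mixtures with per-strain suppression and injected novel peaks, and
  mutated sequence pairs; every simulator attaches ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks (exact
reproduction of the packaged mixture example, seeded synthetic recovery
rates, oracle-equivalence sweeps for UPGMA/NJ, and closed-form checks).

## CLI

```sh
algafp simulate   --seed 1 --n-strains 3 --n-replicates 3 --out-dir out/sim
algafp preprocess out/sim/strain*.txt --out-dir out/pp
algafp fingerprint out/sim/strain*.txt --out-dir out/fp
algafp mixture    --constituents c.tsv --mixtures m.tsv --out-dir out/mx
algafp phylo      alignment.fasta --out-dir out/ph \
                  [--ms-tree tree.nwk --classes classes.tsv]
algafp full       --seed 1 --out-dir out/full
```

Every command archives its effective configuration as
`run_config.json` next to its outputs; a YAML config (`--config`) may
override any default key (unknown keys are rejected). Exit codes:
0 success, 2 validation error, 3 runtime error.

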