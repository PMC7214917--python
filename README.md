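# bolddelay

BOLD delay (hemodynamic lag) perfusion mapping from resting-state fMRI,
with a synthetic ground-truth cohort generator and a scan-length experiment
harness.

## The problem

Perfusion imaging in acute stroke usually needs a gadolinium bolus
(DSC-MRI). The BOLD signal offers a contrast-free alternative: systemic
low-frequency oscillations (sLFOs, 0.01–0.15 Hz) travel with the blood,
so the **time shift that maximizes the cross-correlation between a voxel's
BOLD time course and a venous-sinus reference** acts as a surrogate for
perfusion delay. Hypoperfused tissue shows delays of several seconds;
thresholding the delay map (> 0, > 2.3, > 4.6 s) inside the
stroke-affected vascular territory yields a perfusion-lesion estimate
comparable to a Tmax > 6 s lesion.

This package is for researchers who want to study that measurement itself —
in particular how it degrades as the resting-state scan is shortened — with
full ground-truth control. It provides:

- `bolddelay.synthetic` — 4D BOLD cohorts with a known smooth lag field, an
  ellipsoidal delay lesion, a venous-sinus reference region, a vascular
  territory atlas, a DWI core, and motion traces (NIfTI / TSV / JSON on
  disk, plain arrays in memory);
- `bolddelay.preprocess` — volume discard, rigid-motion confound
  regression, 6 mm Gaussian smoothing, zero-phase 0.01–0.15 Hz band-pass,
  prefix scan segments, FD and DVARS motion QC;
- `bolddelay.lagmap` — per-voxel lag r(d) = corr(voxel shifted by d, ref)
  maximized over d ∈ ±20 s at TR resolution, with a surrogate-calibrated
  significance threshold on the peak correlation;
- `bolddelay.delineate` — territory-constrained lesion delineation at the
  delay thresholds (and > 6 s for Tmax-like maps), 26-connectivity cluster
  filtering, volumes in mL;
- `bolddelay.agreement` — Dice overlap, Bland-Altman bias / 95% limits of
  agreement / percent bias, Cohen's kappa (unweighted and
  quadratic-weighted);
- `bolddelay.experiment` — the end-to-end scan-length study on a synthetic
  cohort, plus the `bolddelay` command line (`generate`, `run`, `report`,
  `qc`).

See `docs/methods.md` for the model, the null-calibration scheme, and every
numerical choice.

## Worked example

```python
import bolddelay as bd

cfg = bd.ExperimentConfig(
    cohort=bd.SyntheticConfig(grid_shape=(24, 24, 12), n_frames=400,
                              lesion_fraction=0.08, snr=8.0, seed=0),
    n_subjects=3, fractions=(0.25, 0.5, 1.0), n_null=200, n_discard=10, seed=7)
report = bd.run_cohort(cfg, "bd_example")

print("median Dice vs full scan, by fraction:")
for frac, d in report.summary["median_dice_by_fraction"].items():
    print(f"  {frac}: {d:.3f}")
row = report.rows[(report.rows.fraction == 0.5)
                  & (report.rows.threshold_s == 2.3)].iloc[0]
print(f"sub-000, fraction 0.5, threshold 2.3 s: volume {row.volume_ml:.2f} mL "
      f"(full scan {row.volume_full_ml:.2f} mL), Dice {row.dice_vs_full:.3f}, "
      f"lag error (median abs) {row.lag_medabs_brain:.3f} s, "
      f"r threshold {row.r_threshold:.3f}")
```

prints

```
median Dice vs full scan, by fraction:
  0.25: 0.000
  0.5: 0.790
  1: 1.000
sub-000, fraction 0.5, threshold 2.3 s: volume 2.12 mL (full scan 3.06 mL), Dice 0.819, lag error (median abs) 0.107 s, r threshold 0.644
```

Reading the numbers: each subject is processed at every scan-length
fraction (discard → confound regression → smoothing → band-pass →
sinus-reference lag mapping → territory-constrained delineation), and each
shortened scan's lesion is compared with the lesion from that subject's
full scan. Here the quarter-length scans are too short to reproduce the
full-scan lesion (median Dice 0.000 — at 100 frames the delineations
collapse), half-length scans recover it substantially (0.790), and the
full scan trivially matches itself (1.000). The per-row line shows one
subject's half-scan lesion (2.12 mL vs 3.06 mL on the full scan,
Dice 0.819), a median absolute lag-recovery error of 0.107 s against the
generator's true lag field (about a quarter of the 0.4 s repetition time,
the quantization floor), and the calibrated significance threshold on the
peak correlation for that segment length (r = 0.644 at α = 0.05 with 200
surrogates).

The same study runs from the shell:

```sh
bolddelay generate --n-subjects 3 --seed 4 --out cohort/   # NIfTI + TSV + truth
bolddelay run --config experiment.yaml --out results/      # rows.tsv, summary.json
bolddelay report results/rows.tsv                          # recompute summaries
bolddelay qc cohort/sub-000/motion.tsv                     # mean FD, FD×10
```

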