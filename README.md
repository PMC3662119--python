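# mammodensity

Fully automated, area-based mammographic percent-density estimation for
"For Presentation" MLO full-field digital mammograms, together with the
statistical toolkit used to evaluate such algorithms against radiologist
panels.

The pipeline mirrors the classic area-based design:

1. **Segmentation** — identify the breast envelope (region of interest)
   by removing the dark background (Otsu), the pectoral muscle
   (laterality-guided corner region growing), overlay text (bright
   components confined to the background) and a subcutaneous-fat margin
   (skin-line erosion that leaves the chest-wall edge untouched).
2. **Thresholding** — select the dense-tissue threshold inside the
   envelope with two classic histogram methods, maximum-entropy and
   moment-preserving, combined by a documented rule (default: rounded
   mean of the two thresholds; alternatives selectable).
3. **Density** — percent density = dense pixels / ROI pixels, mapped to
   the four-level BI-RADS bins (0–24, 25–49, 50–74, 75–100%).
4. **Agreement evaluation** — reference standard as the per-subject
   median of a rater panel; ICC(2,1) with a McGraw–Wong 95% CI and the
   poor/fair/moderate/substantial/excellent interpretation scale;
   quadratically weighted kappa; Pearson correlation; Bland-Altman bias
   and limits of agreement (reference minus algorithm, ±1.96 sample SD);
   within-one-BI-RADS-category proportion; per-category box summaries;
   and the decision rule that flags an algorithm as *promising* when its
   ICC against the reference standard falls inside the panel ICC's CI.

Because no clinical images ship with the package, a **phantom** module
generates synthetic MLO-like mammograms (half-elliptical breast attached
to the chest wall, pectoral wedge, dense blobs painted to an exact target
ratio, optional overlay text, Gaussian noise) with pixel-exact ground
truth, plus a simulator for radiologist panels rating on the 21-point
0–100% grid. Every stage of the pipeline is validated against this
ground truth.

DICOM I/O is self-contained: a minimal reader/writer for single-frame
little-endian (explicit or implicit VR) grayscale images that honors the
View Position (0018,5101) and Image Laterality (0020,0062) elements,
inverts MONOCHROME1 at ingestion, and rejects non-MLO views.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance battery (threshold
oracle equivalence, moment closed-form limit, phantom density recovery,
segmentation fidelity, ICC/kappa correctness, Bland-Altman conventions,
decision rule, BI-RADS boundaries).

## CLI

```sh
# generate synthetic phantoms (DICOM or 16-bit PNG + JSON truth sidecar)
mammodensity phantom --out-dir phantoms --true-density 0.3 --seed 7 --count 5

# estimate percent density for a batch of DICOM mammograms
mammodensity density phantoms/*.dcm --out-dir results --save-panels

# evaluate algorithm densities against a radiologist rating panel
mammodensity evaluate --ratings ratings.csv --densities results/density_report.csv \
    --out-dir evaluation
```

`density` writes `density_report.csv` (one row per image: thresholds,
dense/ROI pixel counts, percent density, BI-RADS category) and a
provenance JSON; failures (e.g. a craniocaudal view in the batch) are
logged and skipped without aborting the batch. `evaluate` expects a
ratings CSV (`subject` column followed by one column per rater) and a
densities CSV (`source_id`, `percent_density`), and writes the agreement
report (JSON + CSV) plus scatter, Bland-Altman and per-category box
figures.

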