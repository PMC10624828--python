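# fetalbiom

Automated fetal biometry and amniotic-fluid assessment from ultrasound
cine-loops.

Routine obstetric screening rests on a handful of measurements taken on
canonical 2-D planes: head circumference (HC) and biparietal diameter
(BPD) on the transthalamic head plane, abdominal circumference (AC) on
the stomach-bubble abdominal plane, femur length (FL) on the full-length
femur plane, and the single deepest amniotic pocket (SDP) for fluid
volume. `fetalbiom` implements the measurement side of that workflow for
*cine-loops* (free-hand video sweeps): given per-frame segmentation
masks from any backend, it scores every candidate frame against
ISUOG-style plane-quality criteria, selects the best frame per loop,
places the calipers, converts pixels to centimetres via the DICOM pixel
spacing, and derives estimated fetal weight and gestational age. It is
aimed at researchers building or validating automated biometry systems:
the segmentation model is pluggable, and a synthetic phantom generator
provides exact ground truth so every stage is testable without clinical
data or trained network weights.

## What it computes

* **HC / AC** — the outer contour of the brain/abdomen mask is fitted
  with a direct least-squares ellipse (algebraic fit with the
  ellipse-specificity constraint `4ac − b² = 1`, numerically stable
  partitioned form); the circumference is the exact ellipse perimeter
  `4a·E(1 − b²/a²)` with `E` the complete elliptic integral of the
  second kind.
* **BPD** — the full minor-axis diameter `2b` of the same head ellipse.
* **FL** — the long side of the minimum-area rotated rectangle of the
  femur mask.
* **SDP** — every pocket on every frame of the amniotic sweep is
  measured (vertical extent of its bounding box) and the deepest is
  retained; oligohydramnios is SDP < 2 cm, polyhydramnios SDP > 8 cm.
* **EFW** (grams), 3-parameter Hadlock:
  `log10 EFW = 1.335 − 0.0034·AC·FL + 0.0316·BPD + 0.0457·AC + 0.1623·FL`
  (lengths in cm).
* **GA** (days), Intergrowth late-pregnancy formula:
  `ln GA = 0.03243·(ln HC)² + 0.001644·FL·ln HC + 3.1813`
  (HC/FL in mm by default; see `docs/methods.md` for a documented
  caveat about this intercept).
* **Best-frame selection** — composite score
  `(w_q·Q + w_z·Z + w_c·C) / Σw` from the mean criterion probability Q,
  the zoom-conformity indicator Z ("structure occupying more than half
  of total image"), and the backend confidence C.
* **Agreement statistics** for method comparison: MAE, Bland-Altman
  bias and 95% limits of agreement (`bias ± 1.96·sd`, optionally as a
  percentage of the pair mean), one-way ICC, paired Wilcoxon
  signed-rank (exact for n ≤ 25), sensitivity/specificity, Dice/IoU.

It also ships an annotation-extraction toolkit that reconstructs
ground-truth measurements from archived stills with burned-in caliper
crosses, dotted measurement ellipses, and OCR'd text.

## Worked example

Generate a synthetic examination (four loops) and measure it end to end:

```bash
for kind in cephalic abdominal femoral amniotic; do
  fetalbiom phantom --kind $kind --seed 7 --out /tmp/exam/$kind
  fetalbiom measure --loop /tmp/exam/$kind/frames --kind $kind \
      --backend phantom:/tmp/exam/$kind --out /tmp/exam/$kind.json
done
fetalbiom report --merge /tmp/exam/cephalic.json --merge /tmp/exam/abdominal.json \
    --merge /tmp/exam/femoral.json --merge /tmp/exam/amniotic.json \
    --out /tmp/exam/full.json
```

The merged report contains (seed 7):

```
EFW 2565.66 g   GA 121.83 days (17w3d)   SDP 4.7 cm (normal)
```

with per-plane blocks like `planes.cephalic.HC_cm = 33.15`,
`planes.cephalic.BPD_cm = 9.00`, the selected frame index, the fitted
ellipse, caliper coordinates, and the full quality assessment
(criterion probabilities, zoom ratio, composite score). The HC/BPD/AC/FL
values agree with the phantom's planted truth to well under 1%; the GA
number is what the printed Intergrowth intercept yields and is
discussed in `docs/methods.md`.

The same pipeline is callable as a library:

```python
from fetalbiom import PhantomSpec, PhantomBackend, generate_biometry_loop
from fetalbiom import measure_biometry_loop, assemble_report

loop, labels, truth = generate_biometry_loop(PhantomSpec(kind="cephalic", seed=7))
backend = PhantomBackend(labels, truth.flags, truth.confidences, degrade_px=2)
report = assemble_report([measure_biometry_loop(loop, backend)])
```

An external deep-learning segmenter attaches through a two-function
adapter (`segment_frame`, `classify_criteria`) referenced by dotted path:
`--backend mypkg.adapters:make_backend`.

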