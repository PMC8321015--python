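# vitimap

Semi-automatic detection of facial vitiligo patches in black-light
photographs, with population-level occurrence mapping.

Vitiligo vulgaris produces depigmented skin patches that are hard to see on
fair phototypes under white light, but fluoresce under ~365 nm ultraviolet
(Wood's lamp) illumination — the standard dermatological acquisition
condition. `vitimap` is a scriptable library + CLI for dermatology research
groups who want objective, reproducible patch detection and cross-patient
statistics from such photographs: the user supplies only a rough polygonal
contour per candidate region and a single global threshold, and the adaptive
algorithm separates vitiligo from healthy skin pixel by pixel.

## Method

Every photograph is rescaled to the fixed 610 × 407 working frame and
mapped to intensities on [0, 1]. A channel-arithmetic filter turns the RGB
image *I = (R, G, B)* into a single-channel image in which fluorescing
(depigmented) pixels are bright:

| filter | definition | use |
|---|---|---|
| 1 | `B` | blue channel alone |
| 2 | `1 − luma(R/B, G/B, B/B)` | blue-normalized complement |
| 3 | `clip(B − R, 0, 1)` | blue minus skin tone |
| 4 | `clip(G + B − R, 0, 1)` | **default** — fluorescence minus skin tone |

Detection then runs independently over each user-drawn polygonal ROI: with
global threshold *T* ∈ [0, 1] and per-ROI maximum gray level
*gₘₐₓ*, the adaptive cutoff is

&nbsp;&nbsp;&nbsp;&nbsp;*t* = *T* · *gₘₐₓ*,

and every ROI pixel with filtered value ≥ *t* is marked vitiligo. Scaling by
the local maximum makes one threshold (default 0.5) work across unevenly
lit face regions; *T* = 0 marks every ROI pixel (manual contouring) and
*T* = 1 marks only the brightest.

For population statistics, each patient's binary mask *mᵢ* is registered
onto a fixed face template through the patient's face-contour ellipse
(per-axis scaling by the ratio of template to patient semi-axes, translation
of centers, rounding to integer pixels), and the occurrence matrix

&nbsp;&nbsp;&nbsp;&nbsp;**M** = Σᵢ *mᵢ*,&nbsp;&nbsp; *i* = 1…*N*,

normalized by the patient count *N*, gives the percentage of patients with
vitiligo at every template coordinate. Sub-populations can be selected by
gender, familiarity, onset age, first-visit year and onset-to-visit delay.

Detected masks are scored against gold-standard masks by the overlap
success rate 100·TP/(TP+FP+FN), and threshold robustness is quantified by
sweeping *T* over 0.35–0.65 and mapping per-pixel detection frequency.

Because clinical photographs cannot be redistributed, the package ships a
seedable synthetic-cohort generator (`vitimap simulate`) that emulates the
acquisition conditions — red-dominant skin, blue/green-boosted patches,
illumination gradients, overexposure, beard texture, hair-strand occlusions
— with exact per-pixel ground truth.

## Worked example

```sh
$ vitimap simulate --n 5 --seed 42 --out demo
wrote 5 synthetic patient(s) to demo

$ vitimap detect --image demo/P001.png --session demo/P001.json --out demo/P001_mask.png
detected 4085 vitiligo pixel(s); patch area = 2.43% of the face-ellipse area

$ vitimap validate --detected demo/P001_mask.png --gold demo/P001_gt.png
tp=4085 fp=0 fn=0 success_rate=100.00%

$ vitimap sweep --image demo/P001.png --session demo/P001.json --out demo/stab.csv
swept 7 thresholds in [0.35, 0.65]; 4085 pixel(s) detected at every threshold

# ... detect P002..P005 the same way, then:
$ vitimap aggregate --cohort demo/cohort.csv --masks demo --sessions demo \
      --out demo/map.csv --render demo/map.png
occurrence map over 5 patient(s) (all patients); peak occurrence 60.0%
```

Reading the numbers: patient P001 carries 4085 detected pixels, 2.43% of
their face-ellipse area; the detection agrees perfectly with the generator's
ground truth (no false positives or negatives), and all 4085 pixels survive
every threshold in the 0.35–0.65 robustness sweep. Aggregated over the
5-patient cohort, the most-affected template cells are shared by 3 of 5
patients (60% occurrence); with 5 patients every cell is an exact multiple
of 20%.

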