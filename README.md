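# marrowdose

Automatic delineation of lumbar-vertebra red bone marrow on low-dose CT and
PET-based estimation of the red-marrow absorbed dose in ⁸⁹Zr immunoPET
studies.

Red bone marrow (RM) is the dose-limiting organ in radio-immunotherapy.
Its activity concentration can be read from PET if the intraosseous volume
of the lumbar vertebrae (LV) can be delineated on the coregistered low-dose
CT — a task that is slow and observer-dependent when done by hand.
`marrowdose` implements the automated alternative: a region-based active
contour finds the outer bone contour of each vertebra slice by slice, an
in-plane morphological erosion strips the cortical shell, and the resulting
intraosseous mask is mapped onto the PET time series to yield time–activity
curves, residence times and RM absorbed dose. Manual cylindrical VOIs and
the fixed-factor plasma method are included as comparators, and a synthetic
CT/PET vertebra phantom makes the whole chain testable without patient data.

## Method

**Delineation.** On the CT rebinned to the 4 mm PET grid, a loose region c₁
(user box around the LV stack, dilated by ~1 cm) seeds, per axial slice, a
Chan–Vese active contour with distance regularisation. The level-set energy
is

```
E(φ) = μ_reg ∫ ½(|∇φ|−1)² + μ_len L(φ) + λ_in ∫_{φ>0} (I−c_in)² + λ_out ∫_{φ<0} (I−c_out)²
```

with c_in/c_out the smoothed-Heaviside region means, recomputed every
iteration, and a fixed 30 gradient-descent iterations. Stacking the slice
results gives the outer bone contour c₂; eroding c₂ in-plane with a
cross-shaped element of radius 1–3 pixels (3 by default) gives the
intraosseous region c₃. Agreement with manual VOIs is quantified by the
Dice similarity coefficient DSC = 2|A∩M| / (|A|+|M|).

**Dosimetry.** For each region the cumulated activity concentration is the
trapezoidal integral of the measured TAC plus a physical-decay tail
C(t_last)/λ (⁸⁹Zr: T½ = 78.41 h). Residence time is cumulated activity per
injected activity, τ = Ã/A₀; the remainder of body closes the balance,
τ_RB = T½/ln2 − Στ. Doses follow the MIRD schema with user-supplied
OLINDA/EXM-style S values: self dose S(RM←RM)·τ_RM, total dose
Σ S(RM←src)·τ_src + S(RM←RB)·τ_RB. The plasma comparator scales a plasma
TAC by the conventional RM-to-plasma ratio 0.19. Effective half-lives are
fitted log-linearly.

## Worked example

Generate a synthetic five-vertebra study (20 HU CT noise, 5 % PET noise),
delineate it, and compute the dose with a placeholder S-value table:

```
$ marrowdose phantom --spec spec.json --out study --seed 1
wrote 12 files to study

$ marrowdose delineate --ct study/ct.nii.gz --box 24,24,23,72,72,213 \
      --grid-like study/pet_00.nii.gz --out masks
c2: 4926 voxels (315.3 mL); masks written to masks

$ marrowdose evaluate --auto masks/c2.nii.gz --manual study/truth_whole_vertebra_pet.nii.gz
DSC = 0.9570

$ marrowdose dose --mask masks/c3_k3.nii.gz --study study/study.json \
      --svalues svalues.json --out dose \
      --pet study/pet_00.nii.gz --sidecar study/pet_00.json \
      --pet study/pet_01.nii.gz --sidecar study/pet_01.json \
      --pet study/pet_02.nii.gz --sidecar study/pet_02.json \
      --pet study/pet_03.nii.gz --sidecar study/pet_03.json \
      --pet study/pet_04.nii.gz --sidecar study/pet_04.json
self RM dose 16.3162 mGy/MBq, total 113.1217 mGy/MBq; outputs in dose
```

The detected outer bone contour overlaps the ground-truth vertebrae with
DSC 0.96. The extracted RM TAC (`dose/tac_rm.csv`) starts at
4958 Bq/mL at 1 h and falls to 1271 Bq/mL at 144 h; its fitted effective
half-life (`dose/effective_half_life.json`) is 72.8 h, recovering the
phantom's 73 h clearance and, as expected, shorter than the 78.41 h
physical half-life. With the placeholder unit S values the "dose" equals
the residence times themselves: self = τ_RM = 16.32 h·S, and total =
τ_RM + τ_RB = 113.12 = T½/ln2, confirming the remainder-of-body closure.
Replace `svalues.json` (see `marrowdose svalue-template`) with tabulated
S values to obtain doses in mGy/MBq.

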