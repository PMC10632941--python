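# Methods

## The measurement model

Under polarized light, cortical bone lamellae form alternating bright and
dark bands whose local thickness varies along their length. The package
models a marked measurement area as a stack of such bands crossed by
vertical pixel columns: after reorientation every column intersects every
band once, so the per-column run lengths of a binarized image are direct
thickness samples, and averaging the *i*-th same-color run across columns
estimates lamella *i*'s mean thickness along its whole visible length.
This positional correspondence is what the two column filters protect: a
column whose first pixel has the minority color, or whose run counts differ
from the operator's band counts, cannot be aligned run-by-run with the
others and is discarded rather than repaired.

Assumptions: one rectangle per image; lamellae approximately parallel and
fully crossing the rectangle; bright/dark alternation (the operator's
counts may differ by at most one); annotation colors exact (lossless image
round-trips).

## Reorientation and cropping

The rotation angle comes solely from the two red fiducials: the corrective
angle makes them share a row, with the 180° ambiguity resolved by requiring
red (top corners) to end up above green. Marker detection groups
exactly-matching pixels by 8-connectivity and rounds each component
centroid to the nearest pixel; with corners ~100 px apart this quantizes
the angle to roughly ±0.3°, which across a 150-px-wide region moves band
boundaries by well under a pixel.

Rotation resamples by nearest neighbor with black fill on an enlarged
canvas. This is deliberate: bilinear blending would destroy the exact
marker colors that the subsequent ROI localization needs. The cost is that
thin annotation lines perforate and occasionally scatter single line pixels
one row inside the rectangle interior. Two consequences are handled
explicitly:

- a row or column counts as part of a yellow line when at least 50 % of its
  span across the yellow bounding box matches yellow;
- marker-colored residue inside the interior is repaired from the nearest
  non-marker pixel in the same column. The residue merely occludes tissue,
  and column-local repair restores it; discarding whole rows instead would
  systematically thin the edge lamellae by a pixel.

The crop is the open interval between the innermost yellow lines on each
side, so the measured area excludes the lines themselves.

## Binarization

Grayscale uses the BT.601 luma weights (0.2989, 0.5870, 0.1140), rounded —
the standard transform, chosen so thresholds are reproducible. The
contrast stretch maps the 1 %/99 % linear-interpolation quantiles to 0/255;
a constant image passes through unchanged. The stretch does not change
which pixels exceed their local mean on two-level synthetic input; on real
material it improves the separability the local threshold works with.

The threshold itself is column-local: each pixel is compared with the mean
of the `window_size` (default 20) nearest row indices in its own column,
excluding the pixel, split 10 above / 10 below and shifted inward at the
image edges so the count stays exactly 20. Equality classes the pixel
**dark** (strict inequality for bright). Column locality means a defect
never influences neighboring columns — the basis of the rejection
semantics below.

Floating-pixel repair is a single top-to-bottom pass per column: a maximal
run of ≤ `max_floating_run` (default 2) pixels lying between two runs of
the opposite color is flipped, the scan continuing on the updated column so
flips can cascade into merges. Runs touching the top or bottom edge are
never flipped — they are not *inside* a lamella.

### The bright-band thickness cap

A consequence of the strict-inequality rule worth stating plainly: in a
perfectly uniform bright band wider than `window_size`, core pixels equal
their neighborhood mean exactly and are classed dark. With the default
repair the measurable bright-band thickness is therefore capped at
`window_size + max_floating_run` = 22 px (≈ 7 µm at 20x); wider uniform
bright bands split and their columns are rejected. Dark bands have no cap
(equality already maps to dark). The 20-pixel window is matched to real
lamellar dimensions at 20x, where this limit is not binding, and real
images carry intensity texture that breaks the exact-equality degeneracy;
the cap is exercised and asserted in the test suite on synthetic two-level
input.

## Measurement

Run-length encoding is exact and per column. The majority first-pixel
color is computed over all columns (ties break to bright). A column passes
when its first run matches the majority color and it contains exactly the
expected bright and dark run counts. One allowance reconciles the
operator's counting rule ("stop at a band mostly cut off by the bottom of
the frame") with the count filter: when a column has exactly one run too
many, its final — bottom-touching — run is treated as that partial band and
dropped from both counting and measurement. This is the
`drop_partial_bottom` flag, default on; without it, images whose last band
is clipped would reject nearly every column.

Averages are reported in micrometers at `pixel_length_um` (default 0.3185
µm, the pixel pitch of the original acquisition at 20x; an input, not a
constant), unrounded internally and serialized to 4 decimals.

## Agreement statistics

Percent differences use the **manual** measurement as denominator — it is
the reference standard the automated method is validated against. The
choice matters to the magnitude of the mean |%diff| summary and is made
explicit here because other conventions (automated, or midpoint) exist.

The paired sign test is exact: zeros discarded, `k = min(#pos, #neg)` of
`n` nonzero differences, `p = min(1, 2·Σ_{j≤k} C(n,j)/2ⁿ)` with integer
binomial coefficients — no normal approximation, since validation datasets
are small-to-moderate. Differences between paired thickness measurements
are typically non-normal, which motivates the nonparametric choice; any
off-the-shelf normality test can confirm this on real data and none is
re-implemented here.

## The synthetic fixture generator

`fixtures.generate_fixture` emulates the operator-annotated input class:
horizontal two-level bands (defaults 200/55, well separated), extended
beyond the rectangle on all sides because real tissue continues past the
measurement area; optional Gaussian intensity noise; circular blob defects
standing in for osteocyte lacunae; a global rotation applied with bilinear
resampling (data generation is not the method under test); and the
annotation stamped *after* rotation — yellow rectangle sides 2 px thick
(as annotation tools draw them; 1-px lines perforate below the 50 % line
rule after de-rotation), single red/green pixels on the corners — so the
marker colors are exact and the pipeline must genuinely undo the rotation.
An optional sinusoidal band profile mimics polarized-light gradation and
stresses the adaptive threshold; the default is hard-edged so tests have
exact boundary oracles.

What passing on these fixtures does **not** show: robustness to staining
variation, uneven illumination, canaliculi texture, curved or wedged
lamellae, or lossy-compressed annotations. The generator constrains
intensities to differ by ≥ 40 levels when noise is on; real image contrast
after the stretch is typically comparable, but no physical imaging model is
claimed.

## Problem sizes and numerical choices

Test fixtures are of order 50–200 px per side — large enough that every
band crosses ~120–140 columns, small enough that brute-force oracles
(naïve double-loop threshold, per-pixel run counters, exhaustive sign-test
enumeration for n ≤ 12) run comfortably alongside the vectorized
implementations they check. Rotation geometry (forward point mapping and
output canvas size) matches `scipy.ndimage.rotate(reshape=True)` exactly,
so generator ground-truth coordinates and pipeline detections agree without
slack. Quantiles are linear-interpolation (`numpy.quantile` default); on
8-bit data the difference from other conventions is below one intensity
level.

Degenerate inputs are errors, not silent defaults: coincident red markers,
missing/ambiguous fiducials, missing or unclosed rectangles, images not
taller than the threshold window, every column rejected (reported with the
tallies of which filter rejected what, and a pointer to re-count lamellae
on the `count_assist` preview), and all-zero difference vectors in the sign
test.

## Known limitations

- Sub-pixel boundaries are not interpolated; each column samples thickness
  at integer resolution and accuracy comes from averaging (±1 px per-column
  worst case near band boundaries under rotation).
- Lamella identity is positional; no cross-column tracking exists, so a
  defect that merges two lamellae without changing the run count (e.g. a
  blob bridging across a thin band, repaired into its surroundings) can
  bias a retained column. The filters catch count changes, not
  count-preserving distortions.
- The bright-band cap described above applies to texture-free input.
- One rectangle per image; no shear or perspective correction; marker
  matching assumes lossless encodings (a per-channel `tolerance` exists for
  images that survived mild lossy handling, but placement precision is then
  the operator's problem).
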