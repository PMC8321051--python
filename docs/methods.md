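# Methods

## Scene model and assumptions

The pipeline analyzes grayscale apical 4-chamber echocardiogram video. It
assumes only the topology of that view: blood pools image dark, tissue
bright; the left atrium is the chamber in the bottom-right quadrant; the
mitral valve lies above the atrial centroid; and the interatrial septum may
be so thin (≤ 1 mm) that it vanishes at the global Otsu threshold. It makes
no anatomical, probe-geometry or frame-rate assumptions beyond these, and
uses no training data. The analysis path contains no randomness: a video
and a configuration determine the report exactly.

## Procedure

**Thresholding.** Otsu's criterion is minimized exactly over the distinct
pixel values present, not over a binned histogram. With intensities on
[0, 1] (enforced at load time) the candidate set is typically small and the
exact scan is cheap; the exactness also makes the implementation directly
checkable against a brute-force enumeration. A pixel `p` is foreground iff
`p ≥ t`. Ties in the objective go to the smallest candidate. A
single-valued image is degenerate: the threshold is that value, objective
zero, everything foreground.

**Background subtraction.** The background is the per-pixel median over all
frames (even frame counts use the midpoint of the central pair). Residuals
`F_n − S` are clipped at zero so the stack remains an intensity image;
negative residuals carry no tissue information here.

**Extreme frames.** The open- and closed-valve frames are found as the pair
of background-subtracted binary frames with maximal Euclidean distance
between foreground centroids, by exhaustive O(N²) pair search; frames with
empty masks are skipped and ties go to the lexicographically smallest index
pair. Binary combination uses logical OR; grayscale combination uses the
pixel mean of the two frames rather than their sum, keeping the combined
image on [0, 1] — a monotone rescaling that leaves Otsu's split unchanged
but keeps the threshold step size meaningful.

**Boundary search.** The search box is the bottom-right `box_frac` of each
dimension. The two thresholds are lowered on the grid
`l_init, l_init − c, …, 0` with l2 innermost (reset for every l1); the
initial pair is tested before any decrement, since thresholds only need
lowering when they were too high to begin with. At each pair the raw and
subtracted combined images are rebinarized and OR-ed; a candidate boundary
is a 4-connected background component of the result that does not touch the
image border (an enclosed hole — 4-connectivity for the background so it
cannot leak diagonally through an 8-connected tissue boundary). The hole
qualifies iff its bounding box spans at least `p·bx` and `p·by` (inclusive)
and lies entirely inside the box. If several holes qualify at the accepted
pair, the largest area wins. Contours are traced with Moore-neighbor
tracing; termination is Jacob's stopping criterion (re-entering the start
pixel from its original backtrack direction), generalized to stop on any
repeated (pixel, backtrack) state because the strict criterion is known to
cycle on 1-pixel-wide protrusions. The atrial centroid is the mean of the
filled hole's pixel coordinates — more robust than a contour-pixel mean,
whose density varies with local boundary shape. If both grids are exhausted
the run fails loudly ("no atrium boundary found") rather than guessing.

**Prongs and σ.** Prong `k` of `npr` (odd, so one prong is vertical) has
angle `θ_k` equidistant on `[−cone/2, +cone/2]` from vertical-up; sample
`j` is `centroid + j·(sin θ, −cos θ)` rounded to the nearest pixel,
`j = 1…⌊length⌋`, duplicates collapsed, samples outside the image dropped.
Hit masks rebinarize every **raw** frame at the accepted `l1`: the leaflets
need the lowered threshold to survive, and a near-stationary leaflet would
be erased by background subtraction. A miss maps to the prong tip,
deliberately inflating σ (touching nothing means the valve is open). σ
aggregates both coordinates, `sqrt(popVar(x) + popVar(y))` with divisor
`npr` — symmetric under translation and axis exchange.

**States and rules.** The σ series is sorted; the threshold is the value
just before the largest adjacent gap (smallest index on ties), so it is
always a member of the series and at least one frame (the minimum) is
always labelled closed. `σ ≤ σ*` is closed — boundary inclusive. If all σ
are equal there is no gap; the degenerate flag is set and every frame is
closed, which a motionless valve deserves. Rule 1 counts overlapping
3-frame windows containing two state changes and fires iff the count
strictly exceeds `transition_frac·N` (exact real-valued comparison, no
flooring); rules 2 and 3 fire iff the closed or open fraction strictly
exceeds `open_close_frac`. Equality is healthy in all three.

## Parameters

| key | default | unit | role |
|---|---|---|---|
| `prong_count` | 5 | — | number of rays; odd keeps one vertical |
| `cone_deg` | 40 | degrees | full cone width, matched to the mitral orifice |
| `box_frac` | 0.6 | fraction | search box size; > 0.5 tolerates cardiac drift past the midlines |
| `contour_frac` (p) | 0.1 | fraction | minimum hole span relative to the box; rejects noise specks |
| `step` (c) | 0.005 | intensity | threshold-lowering step on the unit scale |
| `prong_len_frac` | 0.25 | fraction | prong length relative to atrial bbox height |
| `open_close_frac` | 0.85 | fraction | open/closed dominance cut-off (rules 2–3) |
| `transition_frac` | 0.05 | fraction of N | rapid-transition budget (rule 1) |

All are exposed via YAML config and CLI flags for sweeps.

## The phantom

The generator emulates the features the pipeline actually relies on: four
dark chambers enclosed by bright walls (0.8 vs 0.05 intensity), a 1–2 px
interatrial septum (optionally with a faint segment at a chosen gray level,
which forces the recursive search to lower `l1` below that level before the
atrial boundary closes), two leaflets hinged at the atrial roof that take a
closed pose (thin horizontal bar across the orifice, within prong reach) or
an open pose (vertical flaps along the orifice edges, outside the prong
cone), per-frame multiplicative log-normal speckle (the standard
first-order surrogate for ultrasound texture), and global integer-pixel
jitter. Everything is deterministic given the seed.

Mode schedules: healthy cycles with `cycle_frames`-periodic runs (default
16 frames per cycle, so 64 frames hold 4 cycles with no rapid
transitions); fluttering flips state in runs of 1–2 frames; stenotic is
shut except two brief 2-frame attempted openings; prolapsed is open except
two brief 2-frame attempted closures. The brief opposite-state excursions
in the last two are deliberate: the largest-gap threshold is purely
relative, so a σ series from a valve pinned in a single pose for every
frame contains no gap, and the labelling of its residual noise fluctuation
would be arbitrary. A few genuine opposite-state frames anchor the gap;
clinically, stenosis obstructs rather than abolishes opening, and prolapse
is a failure to close fully.

What the phantom does **not** emulate: anatomical chamber shapes, the
sector (fan) field of view, attenuation and shadowing, spatially correlated
speckle, out-of-plane motion, probe re-angulation, and compression
artifacts of archived clinical video. Passing the phantom study therefore
shows that the algorithmic chain is implemented correctly and is robust to
first-order noise — not that the deployed accuracy on clinical video is
reproduced here.

Geometry scales with frame size, but jitter and speckle are absolute, so
the σ separation between poses shrinks relative to noise in small frames;
the default 256×256 is the validated operating size (192 px degrades
gracefully, 128 px is too small with default jitter).

## Numerical choices and degenerate inputs

- Coordinates are 0-based, x = column rightward, y = row downward; "above
  the centroid" is decreasing y. Reported extreme-frame indices are 1-based.
- Box containment requires the full hole bounding box inside the search box
  on all four sides.
- Threshold grids terminate at an explicit 0.0; exhaustion is an error.
- Identical consecutive combined masks during the scan are skipped (they
  cannot change the outcome), which collapses the inner loop on images with
  few distinct values.
- Even-N medians, Otsu ties, gap ties and extreme-pair ties are all
  resolved deterministically (midpoint / smallest candidate / smallest
  index).
- Unit-test and study problem sizes: phantoms at 256×256×64 for end-to-end
  checks (a run takes under a second), 128 px for the recursion-oracle
  comparisons where classification is not asserted, and 24–32 px masks for
  the flood-fill and Otsu oracle sweeps.

## Known limitations

- The prong origin is fixed from the combined image; the per-frame scene
  may translate under it. Large vertical drift changes hit radii and
  inflates within-state σ spread. Re-anchoring the origin per frame is the
  natural extension.
- The largest-gap threshold assumes the video contains both states; a
  single-state recording yields either the degenerate all-closed labelling
  or a noise-driven split.
- A left atrium outside the bottom-right box (unusual probe orientation)
  is a hard failure by design.
- Video containers requiring an ffmpeg backend are only readable if such a
  backend is installed; PNG/TIFF frame directories and multi-page TIFFs are
  always supported.
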