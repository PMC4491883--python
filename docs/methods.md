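# Methods

This note documents the conventions, algorithms and design choices behind
`pathpaint`, in the order data flows through the package.

## Diagram model

Diagrams use pixel coordinates with the origin at the top-left and y
increasing downward (the SVG convention); a node's position is its shape
center. Compartments are axis-aligned rectangles; the containment invariant
tests the node *center* only, so wide nodes may visually overhang a thin
membrane band — deliberate, because membranes are drawn as thin strips.
Self-loop edges are rejected: autoregulation must be drawn through an
intermediate node, which keeps both Boolean rule derivation and arrow
rendering simple. Edge sense is exactly `activate` or `inhibit`
(the enhansive/repressive vocabulary of perturbation links maps onto the
same two signs).

### The 26-shape roster

The registry is fixed at exactly 26 shapes and is immutable at runtime:

| family | identifiers |
|---|---|
| regular polygons (3–10 sides) | triangle, square, pentagon, hexagon, heptagon, octagon, nonagon, decagon |
| containers | rectangle, rounded-rectangle, ellipse, circle, diamond, elongated-hexagon, pill, chevron, star |
| receptors / membrane | double-circle, cup, membrane-channel |
| biomolecule glyphs | dna, rna, protein, phospho-protein, complex, degradation-sink |

The roster is a package convention (any fixed, documented set of 26 works);
`dna`, `rna` and `protein` glyphs are guaranteed members.

## Measurement tables

Measurements are long-format rows annotated on six dimensions —
`individual, cell_type, condition, dosage, channel, timepoint` — with
timepoints in minutes. The CSV dialect is UTF-8, comma-separated, with
exactly those header names plus `value`; the JSON form is
`{"measurements": [...]}` with the same keys. Readers and writers are
symmetric. FCS binaries are out of scope: per-event data arrives as the same
long format with an `event_value` column and is reduced by
`aggregate_events` (mean, median, min, max; the median of an even-sized
group is the midpoint of the central pair).

`collapse` averages dimensions away with a **single unweighted mean over all
present leaf cells**, not a mean of means. On complete (fully crossed) data
the two coincide and collapsing is order-independent; on ragged data the
single-mean semantics is the one documented and tested. Missing cells are
skipped; a node whose every contributing cell is missing paints as no-data
(grey).

## The painting pipeline

Per channel, the control is drawn from the condition × timepoint table
(rows ordered as conditions were declared, columns by ascending time) after
collapsing individual/cell type/dosage:

* `first_row` — the first declared condition's value at the current time
  (typically the unstimulated control);
* `first_column` — the value at the earliest timepoint (fold over t₀);
  for the condition-collapsed painting path this is the collapsed t₀ mean;
* `table_min` / `table_max` — the table extremum, constant over cells.

Equations are applied to the collapsed statistic (statistic-first), not per
event. The arcsinh equation uses the cytometry-standard cofactor form
`asinh(x/b) − asinh(c/b)` with b = 5 by default (the mass-cytometry
convention; fluorescence users may prefer 150). Domain violations — fold or
log against a zero control, log of a non-positive ratio — yield a no-data
signal rather than an exception, so one bad cell cannot abort an animation.

Colormaps are ≥2 linear-interpolated RGB stops over a finite domain. The
default domain is data-driven (min, max of all painted values in the run),
symmetrized about 0 for the signed equations (log, difference, arcsinh) so
that "no change" sits at the colormap midpoint. Out-of-domain values clamp
to the endpoints; no-data is grey (#808080).

Interpolation is piecewise-linear **in value space** (colors are recomputed
from interpolated values, not blended in color space, so a long traversal of
a three-stop map passes through the middle stop correctly). Two sampling
modes exist: `steps_per_interval` (k frames per keyframe interval; 8
keyframes × 4 steps → 29 frames) and `frames_per_minute` (uniform in
minutes, so the 120→240 min interval gets more frames than 0→1 min).
Keyframe times and values are preserved exactly; any interval with a no-data
endpoint renders no-data throughout its interior.

## Heatmaps, clustering, leaf ordering

A node's heatmap spans two of {individual, cell_type, condition, dosage};
cell (r, c, t) is the mean of the node's channel over the two unselected
dimensions. Clustering profiles per axis label are the concatenation of that
label's grid values across all timepoints, so the ordering reflects temporal
dynamics; NaNs are imputed with the profile mean for clustering only (the
painted grid still shows grey). Clustering is scipy average-linkage over
Euclidean distances, with leaves presented in lexicographic label order so
zero-distance ties merge deterministically.

Optimal leaf ordering is implemented natively as the exact dynamic program
over (subtree, left end-leaf, right end-leaf): among all 2^(n−1) orderings
reachable by flipping internal dendrogram nodes it returns one minimizing
the summed distance between adjacent leaves; cost ties are broken by the
lexicographically smallest label sequence, making orderings deterministic.
The implementation is validated against brute-force enumeration of all
flips for n ≤ 8; the test suite also cross-checks that it is never worse
than scipy's `optimal_leaf_ordering` (equality is not asserted — on some
fixtures scipy's result sits measurably above the enumerated minimum).
Clustering/ordering is off by default and enabled per axis.

## Automatic layout

Layered placement: standard compartments are restacked full-width in
biological order (extracellular, membrane, cytoplasm, nucleus; custom
compartments keep their bounds), then nodes are placed on a padded grid per
compartment, ordered by a few barycenter sweeps over the edge graph. The
grid guarantees the contract directly — centers inside the compartment, no
bounding-box overlaps — and raises a `LayoutError` naming any compartment
whose grid cannot host its nodes. The procedure is deterministic for a
fixed seed (the seed only feeds a tie-break jitter). This is a deliberately
simple native method: the contract is containment + no overlap +
determinism, not global crossing minimization, though a crossing-count test
verifies it beats random placement on average.

## Interchange formats

The diagram JSON document is versioned and canonical (sorted keys, 2-space
indent); unknown top-level fields are preserved on read and re-emitted, so
documents from newer tools survive a round trip byte-identically.

SBML export targets Level 3 with the qualitative-models package: the
diagram carries no kinetics, so nodes become qualitative species (max level
1, compartment preserved) and each signed edge becomes a transition whose
input carries a positive/negative sign. Exported documents are checked
structurally (well-formed XML, correct namespaces, species/transition
conservation). BioPax and CellML are not emitted.

KGML import is offline-file only. Entries with graphics become nodes
(coordinates mapped 1:1 to canvas pixels, one cytoplasm compartment sized
to fit); relations of subtype activation/expression map to `activate` and
inhibition/repression to `inhibit`; every other subtype is skipped, with
the count logged and stored in `diagram.metadata["kgml_skipped_relations"]`.

Boolean rules serialize to a neutral, re-parseable text format
(`B' = (A OR D) AND NOT (C)`), one line per node.

## Boolean simulation

Updates are synchronous and inhibitor-dominant:
`next(v) = OR(activators) AND NOT OR(inhibitors)`. A node with inhibitors
but no activators updates as `NOT OR(inhibitors)` (a pure repression arm
stays interpretable — with empty-OR-is-false semantics such nodes would be
pinned OFF and negative feedback loops could never oscillate); a node with
no regulators at all holds its state, so stimulus nodes act as inputs.
Perturbation links clamp nodes (enhansive → 1, repressive → 0) before every
readout; clamps override the update rule. Attractors are enumerated
exhaustively over all 2^n states (successor table + cycle detection),
capped at n = 20; each attractor is reported from its smallest encoded
state and attractors are sorted by that representative, so output is
deterministic. Perturbation links never alter painted values — they render
as a badge and act only in simulation.

## The synthetic case study

The packaged fixture emulates an LPS-stimulation mass-cytometry time course
in human PBMCs at desk scale: 1 individual, 14 cell types (including CD14−
and CD14+ monocytes, dendritic cells, IgM± B cells, NK cells and CD8+/CD4+
T cells), 2 conditions (unstimulated, LPS), 1 dosage, 14 phospho-channels
(p38, ERK, NF-κB, S6, STAT1, STAT3, STAT5, ITK plus six further canonical
signaling channels — CREB, SHP2, ZAP70, SLP76, PLCγ2, LAT — filling the
roster), 8 timepoints (0, 1, 5, 15, 30, 60, 120, 240 min): 3 136 cells.
One stimulus plus its control is enough to exercise every pipeline path.

Values come from piecewise-linear target curves in arcsinh space
(baseline 0.2), converted to raw intensity via `b·sinh(target)` and
multiplied by seeded log-normal noise `exp(σ·N(0,1))`, σ = 0.15 by default.
The targets encode, by construction: monocyte p38/ERK/NF-κB peaking within
15–30 min; monocyte S6 rising from 120 min and maximal at 240; T/NK
STAT3/STAT5/ITK higher at 240 than at 60 min; B-cell STAT1 maximal at
240 min; everything else flat. At σ = 0 these orderings hold exactly and
the end-to-end tests assert them on painted node values and colors.

What the fixture does **not** emulate: per-event single-cell distributions
(a small separate event generator exists only to exercise aggregation),
realistic channel cross-talk, donor variability, or the full
multi-stimulus panel of a real screen. Passing tests therefore demonstrate
pipeline correctness on data with known structure, not statistical fidelity
to any real dataset.

## Numerical and scale choices

* Frame series are pure functions of their inputs; two identical runs are
  bit-identical (dictionaries preserve insertion order, all iteration
  orders are fixed).
* Cost-tie tolerance in leaf ordering: 1e−12 absolute; containment and
  overlap checks use exact comparisons on float pixels.
* Exhaustive checks scale as 2^(n−1) (leaf orders) and 2^n (attractors);
  the suite uses n ≤ 8 leaves and n ≤ 10 nodes, where both enumerations are
  instantaneous, and the attractor API refuses n > 20.
* GIF assembly quantizes RGB to a palette; color-exactness tests therefore
  sample the RGB raster frames, and GIF tests assert structure (frame
  count, loop flag).
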