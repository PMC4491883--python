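# pathpaint

Paint classical, textbook-style pathway diagrams with multi-parameter
cytometry time courses — and watch them move.

Flow and mass cytometry measure dozens of signaling read-outs (phospho-protein
channels) in thousands of single cells per second, across individuals, cell
types, stimulation conditions, dosages and timepoints. Making sense of such
six-dimensional time courses is easier on top of the pathway a biologist
already has in their head. `pathpaint` is a headless library + CLI that:

* models compartmentalized pathway diagrams (26 node shapes, signed
  activate/inhibit edges, extracellular → membrane → cytoplasm → nucleus
  stacking) with validation and an automatic layout tool;
* ingests long-format measurement tables annotated on the six experimental
  dimensions (individual, cell type, condition, dosage, channel, timepoint),
  including per-event tables reduced by a statistic (mean/median/min/max);
* paints each channel-linked node at each timepoint through a
  control → equation → colormap pipeline, and linearly interpolates
  timepoints into smooth animations (unobserved nodes stay grey);
* attaches small per-node heatmaps over two chosen dimensions, optionally
  ordered by average-linkage hierarchical clustering with **optimal leaf
  ordering** (exact dynamic program over dendrogram flips);
* exchanges diagrams as versioned JSON, SBML Level 3 (qualitative models)
  and KGML (KEGG pathway import), and exports animations as GIF / PNG / SVG;
* derives Boolean rules from the signed diagram and simulates them
  synchronously, with perturbation clamping and exhaustive attractor
  enumeration.

## The pipeline in brief

For an observed node linked to channel *g*, the painted value at timepoint
*t* is

```
v(t) = f( x̄_g(t), c_g(t) )
```

where `x̄_g(t)` is the unweighted mean of the channel over individual, cell
type, condition and dosage; `c_g(t)` is a control drawn from the channel's
condition × timepoint table (`first_row`, `first_column`, `table_min`,
`table_max`); and `f` is one of

| equation   | f(x, c)                     |
|------------|-----------------------------|
| raw        | x                           |
| fold       | x / c                       |
| difference | x − c                       |
| log        | log₁₀(x / c)                |
| arcsinh    | asinh(x/b) − asinh(c/b), cofactor b (default 5) |

Values map linearly onto a colormap (default blue → yellow, i.e. low → high
activity); domain violations and missing cells paint grey rather than
raising mid-animation.

## Worked example

The package ships a deterministic synthetic case study emulating an
LPS-stimulated PBMC mass-cytometry time course: 14 phospho-channels × 14
PBMC cell types × 8 timepoints, with fast monocyte p38/ERK/NF-κB responses,
a slower monocyte S6 rise, late STAT3/STAT5/ITK in T/NK cells and a very
late STAT1 response in B cells.

```python
import pathpaint as pp

cs = pp.generate_case_study(seed=1, sigma=0.0)   # sigma=0: noiseless targets
frames = pp.node_values(cs.table, cs.index, cs.linkmap, cs.diagram,
                        equation=cs.config.equation, control=cs.config.control)
print("keyframes:", frames.times)
for node in ("p38", "S6", "STAT1"):
    print(f"{node:>5}:", ", ".join(f"{v:+.3f}" for v in frames.values[node]))
anim = pp.interpolate(frames, steps_per_interval=4)
print("animation frames:", anim.n_frames())
gif = pp.render_animation(cs.diagram, anim, format="gif")
```

prints

```
keyframes: [0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 240.0]
  p38: +0.000, +0.015, +0.091, +0.286, +0.349, +0.118, +0.048, +0.022
   S6: +0.000, +0.000, +0.001, +0.002, +0.004, +0.007, +0.149, +0.286
STAT1: +0.000, +0.000, +0.001, +0.002, +0.004, +0.007, +0.015, +0.187
animation frames: 29
```

The values are arcsinh fold-changes over each channel's t = 0 control,
averaged over all cell types and conditions: p38 peaks at 30 min (the fast
monocyte response diluted across the 14 populations), S6 rises only from
2 h, and STAT1 jumps at 4 h — so the animated diagram lights up
receptor-proximal kinases first and the late STAT program last. The same
run from the shell:

```sh
pathpaint fixtures case-study --seed 1 --sigma 0 --out demo/
pathpaint paint --diagram demo/diagram.json --data demo/data.csv --out demo/anim.gif
```

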