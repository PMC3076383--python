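# skeinpath

Knot and link analysis of polygonal 3D paths: chain reduction by
generalized moves, geometric construction of Conway skein triples, exact
HOMFLY/Jones/Alexander polynomials with handedness, and protein
C-alpha backbone screening.

## What it does

* **linkcore** — polygonal links (open or closed components), regular
  projections, crossings with oriented signs, intersection matrices,
  plain-text coordinate I/O.
* **msr** — Minimal Structure Reduction: a subpath is replaced by the
  segment joining its endpoints whenever triviality / separability /
  concordance conditions guarantee the ambient isotopy class is
  preserved; moves can delete many points at once; the intersection
  matrix is updated incrementally. Reduction traces and move-length
  statistics are exported.
* **skein** — for a chosen crossing, a clean quadrilateral is grown
  around it on the diagram, rotated, and used to build the crossing
  switch (a perturbed lift over the overpass, perturbation factor
  starting at 0.9 and converging to 1) and the oriented smoothing (two
  opposite quadrilateral sides reconnecting the strands). Recursion over
  candidate crossings (first met as underpass) yields a binary skein
  tree; selection is greedy (smallest switched-and-reduced structure) or
  fixed (first candidate).
* **homfly** — exact two-variable integer Laurent algebra. Convention:
  `l*P(L+) + l^-1*P(L-) + m*P(L0) = 0`, `P(unknot) = 1`, k-unlink =
  `(-(l+l^-1)/m)^(k-1)`. Jones and Alexander arise by substitution.
  Knot names/handedness (U, 3_1, 4_1, 5_1, 5_2, 6_1, Hopf, unlinks) come
  from an embedded table anchored at the right-handed (2,3) torus-knot
  fixture. An independent diagrammatic oracle (`homfly_from_diagram` /
  `homfly_of_gauss`) recurses on abstract planar diagrams with no
  geometry and cross-validates the whole pipeline.
* **protein_io** — C-alpha extraction from PDB text (model 1, first
  altloc), gap splitting (gaps terminate parts, never bridged), direct
  or radial closure, classification, knotted-core trimming.
* **fixtures** — deterministic generators: parametric torus knots and
  figure-eight, braid-closure realisations (5_2, 6_1, Hopf), unlinks,
  minimal stick forms, mirror/orientation flips, connected sums, split
  unions, random protein-like chains with excluded volume.

## CLI

```sh
skeinpath analyze structure.pdb              # per-part knot/handedness/polynomial
skeinpath analyze link.coords --json
skeinpath reduce link.coords -o reduced.coords --trace trace.tsv
skeinpath stats --random 20,80,1 --json      # move-length + tree statistics
skeinpath fixtures emit torus_knot --params 2,3 -n 60 -o trefoil.coords
```

Coordinate files are plain text: one `x y z` per line, blank line
between components, `# closed` / `# open` headers.

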