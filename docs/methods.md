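# Methods

## Structure handling

Structures are read from PDB or mmCIF (gemmi backend). Conventions, chosen
so the contact rule behaves identically across deposition styles:

* **Model 1 only.** The pipeline addresses single crystal/docking
  structures; multi-model files are truncated to the first model.
* **Hydrogens excluded everywhere.** Medium-resolution crystal structures
  carry no hydrogens; including them where present would change contact
  distances between otherwise identical structures.
* **Alternate locations** collapse to the highest-occupancy conformer,
  ties broken by file order.
* **Waters are always dropped.** HETATM residues that are tabulated amino
  acids (e.g. selenomethionine) are kept as polymer residues; free ligands
  are dropped unless `keep_ligands=True`.
* **Author numbering** (chain id, residue number, insertion code) is the
  canonical residue identity; label/entity numbering is not exposed.

## Contact rule and the residue interaction network

Two residues are in contact when the minimum Euclidean distance over all
heavy-atom pairs lies in the **closed** interval [d_min, d_max], default
**[2.5, 5.0] Å**. Design choices where the underlying convention is not
published:

* *Closed interval.* "Between 2.5 and 5 Å" is read inclusively — the
  conservative superset; users can reproduce the open convention by
  nudging the bounds.
* *All-heavy-atom minimum*, not Cβ–Cβ or centroid distance: the least
  lossy reading of "distance between residues". A k-d tree over all atoms
  prefilters candidate pairs; every surviving pair is then measured
  exactly, so the result equals the brute-force double loop.
* *Sequence neighbours kept.* Peptide-bond neighbours fall inside the
  window and are genuine geometric contacts; RIN tools differ here, so
  `include_sequence_neighbors=False` suppresses |Δseq| = 1 same-chain
  edges.
* Edges carry the minimum distance as annotation but are **unweighted**
  for centrality.

## Betweenness centrality and Z-scoring

Betweenness is computed on the undirected, unweighted graph with each
unordered pair {s, t} counted once and disconnected pairs contributing
nothing. Z-scores standardise bc within one structure; **z ≥ 2**
(inclusive) flags a residue as central.

* `sd_mode` selects the sample (n − 1, default) or population divisor;
  the convention of the commonly used Cytoscape app is unpublished, so
  both are provided and the mode is recorded in output metadata.
* Z-scores are invariant under any positive rescaling of bc, so the
  unordered-vs-ordered pair convention (which exactly doubles bc) cannot
  change central calls. This is property-tested.
* Constant bc (including single-node graphs) has sd = 0; all z are
  defined as 0 and nothing is central.

## Differential candidate criterion

candidate ⇔ interface ∧ central-in-complex ∧ ¬central-in-reference.

* *Interface* = receptor residue with ≥ 1 partner-chain contact under the
  same window as the RIN.
* *Complex centrality* is computed on the full complex graph (receptor and
  partner nodes together); partner residues can be central but are never
  candidates.
* *Reference* defaults to the receptor chains extracted from the complex
  coordinates — the natural reading of "the receptor's native structure"
  when no independent crystal form is supplied; `--reference` accepts one,
  matched by author numbering with the residue name ignored (so point
  mutants still pair up). Residues present in only one model are flagged
  `mismatch` and excluded from candidacy rather than silently dropped.
* The Z threshold applied to the reference defaults to the complex
  threshold but is an independent parameter.

## Zone scanning and peptide constructs

`split_zones` tiles a sequence into n contiguous zones whose lengths
differ by at most one, with the remainder assigned to the **C-terminal**
zones. This is the unique "approximately 10 residues" split of the 42-mer
CD44v3 exon region that reproduces the four published zones (10/10/11/11).
Deletion constructs, wild-type-checked point mutants (H112A-style) and
seeded composition-preserving scramble controls (re-drawn until they
differ from the input, when possible) are pure string operations with
round-trip guarantees.

Pairwise global alignment uses Needleman–Wunsch with affine gaps
(BLOSUM62, open 10, extend 1 by default — the published comparison names
its alignment program but not its parameters, so reported identity values
for divergent regions should be treated as convention-sensitive).
Percent identity = identical columns / columns excluding gap–gap.

Two polarity tables are shipped: `standard` (conventional side-chain
chemistry; glycine nonpolar) and `published` (the classification used in
the original hydrogen-bonding argument, which counts glycine polar). The
divergence is surfaced, not hidden.

## Binding isotherm

The 1:1 law of mass action R([L]) = r_free + (r_bound − r_free)·[L]/(Kd+[L])
is fitted by bounded trust-region least squares over (Kd, r_free, r_bound).

* Initialisation: r_free = first response, r_bound = last, Kd = the
  concentration nearest half-amplitude. Kd is bounded to
  (0, 10⁴ × max concentration].
* A Hill coefficient is deliberately not fitted: on ≤ 16-point titrations
  a fourth parameter is overparameterised, and a single-Kd readout implies
  one site.
* The 95% CI on Kd uses the covariance at the optimum with a t quantile
  (n − 3 df).
* Binding verdict: fitted amplitude |r_bound − r_free| strictly greater
  than k_sigma (default 3) × residual standard deviation. A perfectly flat
  response returns a non-binding result, not an error.
* Concentrations are nM throughout; the fit is equivariant under
  concentration rescaling and invariant under affine response transforms
  (both property-tested).

The tumour-volume utility defaults to the published caliper formula
π/6·l·w·(1+w)/2 with a `conventional` switch for the usual ellipsoid
reading π/6·l·w·(l+w)/2; the published form is suspected typographical
but honoured as the default.

## Synthetic data

The generators produce every input class the pipeline consumes, with
ground truth known by construction:

* **Toy structures** place one CA atom per residue, so the inter-residue
  minimum distance equals the placement distance and contact graphs are
  exactly designable (star complex, lines, random placements in a box).
  They do not emulate side-chain geometry, packing density or crystal
  artefacts — passing tests demonstrate correctness of the graph
  machinery, not robustness to real-structure pathologies (missing atoms,
  occupancy anomalies), which the loader handles separately.
* **Random graphs** are seeded Erdős–Rényi G(n, p) on synthetic residue
  labels, used as centrality-oracle fodder.
* **Titrations** evaluate the isotherm at given concentrations and apply
  multiplicative Gaussian noise (response × (1 + ε), ε ~ N(0, cv)). The
  default study condition is 11 log-spaced concentrations spanning
  0.1–1000 nM, cv = 0.02, 200 replicates — a realistic thermophoresis
  dilution series around a ~10 nM affinity. Real assays also carry
  concentration errors and baseline drift, which this generator does not
  model.

All generators are pure functions of their arguments including the seed.

## Numerical and testing choices

* Betweenness is cross-checked against an independent matrix-power
  path-counting oracle on every connected graph with ≤ 7 nodes plus 100
  seeded random graphs (n ≤ 12), agreement to 1e-9.
* The contact rule is cross-checked against an exhaustive double loop on
  100 seeded toy structures.
* Float output in artifacts uses 6 significant digits so reruns are
  byte-identical.
* Alignment traceback ties resolve to the aligner's deterministic first
  alignment.

## Known limitations

* Docking, pose minimisation/scoring and de novo peptide folding are out
  of scope; the complex structure is an input.
* Only betweenness centrality is offered; the hotspot criterion as
  published uses no other centrality.
* The headline structural nomination depends on an unreleased docking
  pose, so it cannot be reproduced bit-for-bit from public inputs; the
  star-complex fixture reproduces the *criterion* exactly on a graph whose
  centrality values are known in closed form.
* Pairwise alignment only — no multiple sequence alignment or
  phylogenetics.
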