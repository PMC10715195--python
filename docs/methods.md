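# Methods

## Scope and model

`srbkit` treats a class B scavenger receptor (SR-B) operationally: a protein
is a bona fide SR-B iff it has an included CD36 domain hit and two
transmembrane (TM) helices flanking that domain, one ending no later than
`max_overlap` (default 10 aa) past the domain envelope start and one starting
no earlier than 10 aa before the envelope end. The ectodomain is the region
strictly between the two TM helices. For proteins with multiple CD36 domains
the *first* domain (smallest envelope start) defines the architecture and the
ectodomain. A sequence that satisfies the architecture but carries an
N-terminal tail longer than `max_n_tail` (default 400 aa) before TM1 is
labelled `fused_suspect` rather than SR-B: long foreign N-terminal regions
are the signature of gene-model fusions, and such models need locus-level
curation that no program should silently perform.

All coordinates are 1-based inclusive, matching the table formats consumed
(hmmsearch per-domain output, TMHMM short output, PDB residue numbers).
Envelope (not alignment) coordinates bound the homologous region in the
domain tables. The per-domain dialect has no explicit inclusion column, so
`included` is derived from the full-sequence E-value against hmmsearch's
default inclusion threshold (0.01); the generic TSV dialect carries the flag
explicitly.

Duplicate removal collapses exact string duplicates *within* a taxon only
(keeping the lexicographically smallest id); cross-taxon duplicates are
biology, not redundancy. Isoform collapse beyond exact duplicates is not
automated — it is inherently a curation step — but same-locus id prefixes can
be flagged downstream.

## Hydropathy TM predictor

When no TM table is available, TM helices are predicted from Kyte–Doolittle
mean hydropathy in a sliding window (width 19, cutoff 1.6, both
configurable). A *segment* is a maximal run of window centres whose mean is
at or above the cutoff; runs shorter than 12 residues are discarded and runs
longer than 40 are trimmed to the 21-residue window of maximal mean. The
segment is the centre run itself (not the run expanded by half a window):
for a 30-residue hydrophobic island this reports the island minus ~3 residues
per side, which keeps the segment inside the true helix — the property the
architecture rule needs. Unknown residues (X) score 0.

## Ectodomain analytics

Ectodomain length is the primary comparative signal: compact (metazoan-like)
ectodomains cluster in the ~370–620 aa range while expanded forms reach
>2,000 aa, and lengths above the `flag_threshold` (default 500 aa, strictly
greater) flag candidate lineage-specific expansions. X→A sanitization (with a
reported replacement count) is applied only when preparing sequences for
structure-prediction export, since alanine is the conventional non-bulky,
non-reactive placeholder; census and alignment stages keep the original
residues.

## Alignment analytics

Conventions that the literature leaves open are fixed here explicitly:

- **Consensus**: per column with non-gap occupancy ≥ 0.5, emit the modal
  residue, ties broken alphabetically. Simplest reproducible rule; both the
  occupancy cut and the tie-break are parameters.
- **Pairwise identity**: identical columns divided by columns where *both*
  rows hold residues; pairs with no co-occupied columns contribute 0 and are
  effectively flagged. Identity values are convention-dependent, so the
  denominator choice is stated rather than implied.
- **Conservation**: modal non-gap residue count over *total* rows (an all-gap
  column scores 0), with a ≥40% mask available for display.
- **Gap filter**: a column survives iff its gap fraction ≤ 0.8. This is a
  declared simplification of block-based alignment trimming; the surviving
  original column indices are returned so coordinates lift back exactly.
- **Expansion columns**: for a focal row against a reference row, maximal
  runs of ≥ `min_run` (default 10) consecutive focal residues sitting in
  reference-gap columns, reported with the flanking reference residue
  anchors. Interior columns where both rows are gapped do not break a run.
- **Bridge cysteines**: reference disulfide-pair positions are lifted to
  alignment columns and each row is scanned at those columns ± 2 (nearest
  offset first, left before right on ties). Both cysteines found ⇒ present —
  *unless* a matched cysteine lies inside that row's expansion run, in which
  case the pair is excluded as a false positive: a cysteine supplied by a
  lineage-specific insertion cannot be homologous to the reference bridge.
  Reference pair positions are runtime inputs, not constants.

## Motif scanning

Motifs are position weight matrices in MEME minimal format. Letter
probabilities become log₂-odds weights against the file's background with
pseudocount 0.01 (MEME-suite convention). The sequence score is the best
window sum; a window position is reported and the match flag compares the raw
score with the motif's match threshold (an optional `MATCH_THRESHOLD` line in
the file; 0 when absent). Unknown residues score the background-expected
weight of their position. For display, raw scores map linearly onto 0–100
against the motif's theoretical extrema (the sums of per-position
minimum/maximum weights), clipped, with the no-hit sentinel at 0. This
transform is deterministic and dataset-independent — the published 0–100
heatmaps do not state their transform, so ours is a declared substitute —
and it is invariant under adding a constant to all weights of a position.

## Structure comparison

Superposition alternates two steps until the residue pairing reaches a fixed
point (or 20 iterations, flagged non-converged): a Kabsch least-squares
rigid fit (SVD, reflections corrected to proper rotations) on the current
pairs, then a re-pairing by dynamic programming over the cα distance matrix
that maximizes the number of chain-order-preserving pairs within `d_pair`
(default 5.0 Å) and, among those, minimizes the summed distance. Monotone
matching preserves chain order; 5 Å keeps diverged-but-homologous residues
pairable. The seed pairing comes from a global sequence alignment of residue
types (BLOSUM62, gap open −11 / extend −1) or, for same-length controls,
from equal residue ranks.

Per-pair distances are binned high (< 1.5 Å), medium (1.5–2.7 Å, closed
interval) and low (> 2.7 Å) — the resolution-style categories used for
coloring structural comparisons. Query residues in no pair are *unaligned*;
maximal unaligned runs of ≥ 10 residues become expansion segments with their
flanking paired reference anchors (terminal runs carry a one-sided anchor and
a flag). pLDDT classes use the community 90/70 bounds (lower bound
inclusive); the pTM gate keeps models with pTM > 0.7 and logs the skip list,
passing models with no recorded pTM. All-atom RMSD uses atoms with matching
names within paired residues, which stays well-defined under differing side
chains.

## Cavity detection

A two-probe grid scheme replaces alpha-shape cavity detection while keeping
the same probe radius (0.9 Å). A grid point is accessible to a probe of
radius r iff no atom centre lies within (van der Waals radius + r); vdW radii
are fixed per element (C 1.70, N 1.55, O 1.52, S 1.80 Å). Bulk solvent is the
boundary flood fill of bulk-probe (3.0 Å) accessible points, *dilated by the
bulk probe radius* via a Euclidean distance transform — the rolling-probe
surface, which removes the thin small-probe-accessible film that otherwise
hugs any molecular surface. Candidate voids are small-probe-accessible
points outside that covered region; 6-connected components are classified by
their mouths (26-connected patches of void points adjacent to the covered
region): 0 ⇒ enclosed cavity, 1 ⇒ pocket, ≥ 2 ⇒ tunnel. Volume is voxel
count × spacing³. The dilation distance is Euclidean and does not respect
occlusion, so a cavity closer than 3 Å behind a wall would be eaten; walls of
one atom layer plus probe radii are already thicker than that. Absolute
volumes from grid and alpha-shape methods are not comparable — only
presence and classification semantics are.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all tests:

- **Proteomes**: SR-B-like sequences are N-tail | TM1 (21 aa from {I,L,V,F}
  with occasional A) | ectodomain | TM2 | C-tail. Non-TM regions draw from
  residues with Kyte–Doolittle values ≤ −0.4, so no window outside a TM can
  approach the detection cutoff: truth labels and the hydropathy predictor
  cannot disagree by construction. Ectodomain base lengths default to
  380–480 aa with optional planted insertions at a fixed anchor; planted
  motifs and cysteine pairs use ectodomain-local coordinates. Each decoy
  class violates exactly one architecture condition (no TMs, one TM, an
  800 aa fused N-tail, or no CD36 hit). What this does *not* emulate:
  realistic amino-acid composition, homology between family members, partial
  or noisy domain envelopes, or borderline hydropathy — census accuracy of
  100% on these fixtures demonstrates rule correctness, not robustness to
  ambiguous real data.
- **Gold alignments** are built constructively (ancestor columns plus one gap
  block per lineage insertion), never by running an aligner, so truth columns
  are exact. Substitutions never create or destroy bridge cysteines except
  where the config says so. Real alignment jitter and misalignment are out of
  scope; the ±2-column bridge tolerance absorbs small jitter only.
- **Structures** are cα-only traces: ideal α-helices (rise 1.5 Å/residue,
  100°/residue, radius 2.3 Å), straight cylinder-wall strands (rise 3.8 Å)
  for the barrel, and an optional expansion helix inserted into the chain and
  placed pointing away from the core centroid (≥ 5 Å from every reference
  cα, so the planted insertion is genuinely unalignable). Noise is isotropic
  per-coordinate Gaussian; consecutive cα–cα distances hold to
  3.8 ± 3·√2·σ within segments, while junctions between strands and helices
  are jumps (turns are not modelled). No side chains, no packing, no
  secondary-structure prediction.
- **Cavity shapes** (solid rod, open tube, closed Fibonacci-lattice shell)
  have analytic void truths; the shell's atom sphere sits at inner radius +
  vdW + small-probe radius so the probe-accessible interior is exactly the
  declared ball.

## Numerical choices and problem sizes

- Kabsch rejects < 3 points and degenerate (collinear) sets via singular
  value ratio < 1e-9. The independent cross-check is Horn's closed-form
  quaternion solution (eigen-decomposition), agreeing to < 1e-8 Å RMSD on
  random point sets of 10–200 points.
- The matching DP encodes (pair count, −summed distance) lexicographically
  as `1e7 − d` per pair, valid while any achievable summed distance stays
  far below 1e7 (true for d ≤ d_pair and chains below ~10⁶ residues).
  Traceback uses exact float equality on recomputed cell values, which is
  safe because identical operations produce identical floats.
- Simulation scales: geometry oracle 200 point sets; expansion recovery 200
  structure pairs of ~120 core residues with insertions of 15–60; motif
  oracle 500 random (sequence, PWM) pairs; census fixture 216 sequences;
  cavity grids at 0.5–0.8 Å spacing over ~30 Å boxes. These sizes give
  stable statistics while keeping the full suite fast.
- Under one-sided per-coordinate noise σ the paired-core RMSD-cα after
  fitting is ≈ σ√3·√(1 − 2/N) (≈ 0.515 Å at σ = 0.3, N ≈ 120); the test
  suite asserts this relation rather than a smaller bound, since no rigid
  superposition can beat it in expectation.
- Determinism: all randomness flows through seeded `numpy` generators;
  output tables are sorted and written with fixed float formatting, so equal
  configs and seeds give byte-identical bundles.

## Known limitations

Architecture calls depend on upstream domain and TM annotations; topology
orientation (inside/outside) is not inferred. The gap filter is a gap-fraction
rule, not a block heuristic. Superposition is rigid — flexible or hinged
comparisons will show inflated RMSD and spurious unaligned runs. Mouth
counting is grid-resolution dependent for voids near the spacing scale.
Profile-HMM search, multiple-alignment computation, motif discovery,
structure prediction and phylogenetic inference are all upstream tools whose
outputs this package consumes.
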