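# Methods

## Model and assumptions

The pipeline treats each cross-species homolog group of TFBS predictions
as a binary character (present/absent) on a rooted species tree and asks
where in evolution the site — and co-located groups of sites — arose or
disappeared. The underlying assumptions are the usual ones of
phylogenetic footprinting: orthology of the aligned regions, an
alignment good enough that homologous sites occupy overlapping columns,
and that motif-model matches are a usable proxy for binding. The input
alignment is authoritative: no realignment is attempted.

## Motif scanning

A PSSM's counts `c[i][b]` are converted to log-odds in bits:

    lo[i][b] = log2( (c[i][b] + p·q_b) / (N_i + p) / q_b )

with background `q` (default uniform), total pseudocount `p` (default
1.0, distributed by background) and column sum `N_i`. Both strands are
scored at every offset; the reverse strand scores the reverse
complement, with matches reported in forward coordinates. Match strength
is the matrix similarity score

    mss = (S − S_min) / (S_max − S_min) ∈ [0, 1]

where `S_min`/`S_max` are the column-wise minimal/maximal log-odds sums;
mss = 1 exactly at the consensus, and the score is invariant under
adding a constant to any column. The default reporting threshold is
mss ≥ 0.8. Windows containing non-ACGT characters are skipped with a
warning rather than scored. E-value statistics are out of scope; mss and
the branch length score cover filtering.

Matrices may carry a taxon group ("vertebrates", "plants", …); a clade
filter removes models outside the allowed groups. Matrices without
taxon metadata pass the filter with a warning — permissive, to avoid
silently discarding user matrices.

## Coordinates

All internal coordinates are 1-based inclusive; `seq` positions count
non-gap characters of one row, alignment columns include gaps. The
0-based half-open convention appears only in BED export:
`chromStart = anchor_start − 1 + (seq_start − 1)`. Multi-block MAF input
is concatenated per species, with species missing from a block padded
with gaps so columns remain comparable.

## Clustering and homology

Within one species, two predictions are redundant iff they have equal bp
length, share the start, middle (`⌊(s+e)/2⌋`, integer division) or end
alignment column, and their digit/punctuation-stripped lowercase names
are equal (Sox2 and Sox17 both → "sox") or the factors share a group in
a local homology table. Clusters are connected components of this
relation; the relaxed alternative links any simply-overlapping pair with
compatible names. Clustering can be disabled entirely (singleton
clusters).

Across species, clusters are homologous iff they essentially overlap —
the closed column intervals `[s, s+l]` (beginnings) or `[e−l, e]`
(endings) intersect — and the name/homology condition holds. Comparing
the l-sized flanks rather than whole spans prevents a prediction that
merely brackets a long insertion from being linked to everything inside
it. If one component captures two clusters of a species, the one with
the higher best-member mss is kept and the conflict logged; all
tie-breaks are by (species, s, e, matrix id) so output is independent of
input order.

## Ancestral reconstruction

Fitch parsimony, two passes. Bottom-up, a node's state set is the
children's intersection when non-empty, else the union; for polytomies
this generalises to the states attaining the maximum count over
children (ties keep both), which reduces to classic Fitch on binary
nodes. Top-down, the root resolves ties to *absent* (conservative:
prefers inferring gains, the orientation of the whole analysis), and a
child adopts its parent's state whenever its set allows. On binary trees
the resolved labeling attains the exhaustive minimum number of changes
(verified against full enumeration in the tests). Leaves with sequence
data but no site are absent; leaves with no alignment row are either
treated as absent (default) or excluded from the reconstruction
(`missing='exclude'`).

One consequence of the event representation: a character present in
every leaf is constant — present at every node with zero events — so a
"gain at the root" is never emitted. Parsimony cannot place an origin
older than the root anyway; the tabulated origin of such characters is
simply undefined.

## Pattern mining and the branch length score

Events are bucketed by (node, event type). By default only gains are
mined (losses are disproportionately produced by alignment gaps and
parsimony's known loss-proneness) and events on extant species are
ignored. Within a bucket, characters form a compatibility graph with an
edge where the pairwise spacing — start-to-start distance in ungapped
species coordinates — is identical in every species carrying both (and
at least one such species exists). Every maximal clique of size ≥ 2 is
emitted as a pattern; enumeration order is deterministic (members by
footprint start, cliques lexicographic). Buckets are small in practice,
so exact clique enumeration is feasible; tests compare against full
subset enumeration up to 12 characters. A module gained independently at
several nodes yields one pattern record per origin.

BLS sums branch lengths inside the *maximal* subtrees whose leaves all
carry the prediction, stem branches excluded; a single-leaf prediction
scores 0. The alternative spanning-subtree reading (including stems up
to the connecting ancestor) was considered and rejected: the adopted
clade reading makes the three hand-checkable values on
`((A:0.1,B:0.2):0.3,C:0.4)` — 0.3 for {A,B}, 1.0 for all, 0.0 for a
singleton — exact. BLS is monotone in the presence set.

## Figures

Species colours follow a hue gradient along the leaf order over a 0.75
arc (capped below a full turn so the first and last leaves stay
distinguishable); internal nodes average their descendant leaves' hues;
brightness scales with depth so the root is darkest. The homology-based
figure draws each group once — glyph intensity encodes mss; overlays
under the glyph are thin species-gradient segments for extant
predictions and thick pattern-coloured segments where a displayed
pattern is supported — and shows at most 10 patterns (by BLS) by
default. The alignment-based variant repeats the glyph layer per
species with only the thick pattern segments. Tree logos colour the
origin node and all full-pattern leaves with the pattern colour. All
figures are plain SVG written with the standard library XML tools.

## Synthetic scenarios

`plant_modules` emulates exactly the structure the miner assumes:
modules of exact consensus motifs inserted at fixed spacings into the
sequences of every leaf below a randomly chosen internal origin node,
embedded in i.i.d. uniform background over a shared coordinate frame
(a gapless alignment). Defaults: 300 bp region, 8 bp motifs, module
sizes cycled from (3,), spacings 10–18 bp, branch lengths uniform on
[0.05, 0.5]. Three deliberate identifiability choices:

- module origins are planted at *distinct* non-root internal nodes —
  two modules at one node are, by definition, a single larger module,
  and a root origin produces no gain event (see above);
- chance exact copies of a planted consensus in the background
  (probability ≈1% per motif and leaf over both strands) are scrubbed
  by a single deterministic base change, since an exact copy is
  indistinguishable from a planted site;
- recovery runs scan at mss ≥ 0.95, i.e. only exact 8/8 matches, which
  is the appropriate operating point when planted motifs are exact
  consensus insertions (the general pipeline default remains 0.8).

The noise model deletes or shifts (by 1–3 bp) one member per affected
(module, leaf) with the given probability; a shift keeps the member in
its homolog group but breaks the conserved spacing. What passing
recovery tests show is therefore that the machinery is exact under its
own model — aligned orthologs, unmutated motifs, clean columns. They do
not show robustness to substitution noise, indels/alignment error, or
motif degeneracy, which real data have in abundance; parsimony's
loss-overfitting on noisy alignments is a known limitation inherited by
any result on real alignments.

Everything is driven by numpy's seeded PCG64 generator; identical seeds
reproduce byte-identical scenario files on any platform.

## Problem sizes in the checks

The shipped verification uses: all rooted binary tree shapes to 6
leaves × all leaf labelings (≈64k instances) plus 200 random 8-leaf
instances for Fitch; 100 random buckets of ≤ 12 characters for the
miner; 50 random (≤ 1 kb sequence, matrix) pairs for the scanner; 1000
random gapped rows for coordinate round-trips; and 20 replicates each
of noise-free and 30%-noise planted scenarios (8 species, two modules).
These sizes keep the full suite in the tens of seconds while the
exhaustive oracles remain genuinely exhaustive.
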