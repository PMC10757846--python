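# Methods

This note records the models and procedures `timegraft` implements, the
numerical conventions it adopts, and what its synthetic-data tests do and
do not demonstrate about real data.

## Tree model and Newick conventions

A chronogram is stored as node *ages* (myr; tips at 0), not branch
lengths. Branch lengths are derived (`parent.age − node.age`), so prune
and graft operations move pointers without arithmetic and therefore
preserve all untouched divergence times bit-for-bit — which is what makes
the exact (≤ 1e-9 myr) prune/re-graft inversion tests meaningful.

Newick input is parsed with dendropy; output is written with 6-decimal
branch lengths. On reading a timed tree, root-to-tip depths must agree to
a relative tolerance of 1e-4 of tree height (hand-digitised published
figures carry limited precision); node ages are then rebuilt as mean path
lengths to descendant tips, which is exact for exactly ultrametric input.
Because 6-decimal writing rounds each branch by up to 5e-7, ages
reconstructed after a write/read cycle can drift by roughly
depth × 5e-7; the round-trip tests assert a 2e-5 bound for the tree sizes
they use. Polytomies are accepted and preserved by I/O; only assembly
*output* is required to be binary, and the isolation statistic refuses
polytomous trees outright.

## Grafting rules

For a sister-mode instruction (species, anchor tip, pendant length PL):

* PL < *p* (the anchor's current pendant length): a new node is inserted
  on the anchor's terminal branch at age PL; both tips end with pendant
  length PL.
* PL ≥ *p*: attaching at PL would collide with (or pass) the anchor's
  parent, so the attachment is placed at *p* − ε and both pendant
  lengths become *p* − ε exactly. ε is interpreted in myr (default 0.1),
  and subtraction is the only direction that both avoids a polytomy and
  keeps the tree ultrametric. If *p* − ε ≤ 0 the instruction is skipped
  and reported.

Genus-base mode (used when taxonomic uncertainty precludes naming a
sister species) attaches the new tip on the genus' stem branch at the
midpoint between the genus crown age and its stem age. No principled age
exists for such placements; the midpoint is the unbiased default and the
attachment rule is isolated behind `AssemblyConfig` so sensitivity
analyses can swap it.

Instructions are applied strictly in input order and later instructions
may anchor on species grafted earlier; the CLI additionally orders
instructions sharing an anchor by descending PL so nested attachments
apply outside-in. Failures never abort a run; `AssemblyReport` partitions
every instruction into grafted/skipped and logs each conflict.

## Backbone merging

`merge_backbones` keeps the primary topology. Node matching uses clades
restricted to the shared taxon set, and a match always pairs the two
trees' *MRCAs* of the same restricted set — nested nodes that restrict to
the same set are deliberately not matched, otherwise several primary
nodes would collapse onto one secondary age. Matched nodes take the
arithmetic mean of the two ages. Averaging can invert a parent/child
pair when the trees disagree strongly; the repair raises the parent to
child age + ε, preserving the averaged tip-ward ages that dominate
downstream comparisons. Taxa unique to the secondary tree become graft
instructions (anchor = closest shared tip, PL = attachment age in the
secondary tree). Weighted averaging over more than two sources and
topological conflict resolution are out of scope: the primary backbone
always wins.

## Synthetic data

* **Birth–death simulation** runs forward from two crown lineages with
  rates λ (speciation) and μ (extinction) per lineage per myr,
  conditioning on n surviving tips by rejection; the present is placed
  uniformly within the waiting interval after the lineage count first
  reaches n, and extinct lineages are pruned. This "first passage +
  uniform offset" stopping is a slight simplification of
  general-sampling approaches; the rate-recovery tests bound its bias
  (mean λ̂ within a few percent of truth at n = 200).
* **Graft scenarios** prune k tips sequentially, each drawn from the
  tips currently in a cherry — the one situation in which the recorded
  (sister, PL) pair identifies the attachment point exactly — and emit
  instructions in reverse pruning order. With no induced conflicts the
  scenario is exactly invertible, the headline oracle for assembly. A
  requested `conflict_fraction` of instructions instead ask for
  1.5× the anchor's backbone pendant length, guaranteeing the offset
  rule fires.
* **Relaxed clocks** multiply each branch duration by an i.i.d.
  lognormal rate with mean 1 and log-sd σ; σ = 0 reproduces durations
  exactly.
* **Alignments** evolve sites under Jukes–Cantor along a substitution
  tree, then replace a fixed fraction of cells with gaps.

Defaults used by the test suite and the acceptance script: backbone
sizes 50–200 tips, 5–20 tips pruned per scenario, λ in 0.15–0.35/myr
with turnover up to 0.5, rate noise σ = 0.1, Yule recovery at λ = 0.2
and n = 200 over 20 seeds — magnitudes typical of a primate-scale
radiation (crown age a few tens of myr, a few hundred species). These
sizes keep the full suite under a minute on one CPU.

What the generator does *not* emulate: gene-tree/species-tree discord,
correlated (autocorrelated) rate variation, fossil or sampled-ancestor
data, non-JC substitution processes, and the curation noise of real
published figures. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model, not
robustness to every failure mode of literature-mined trees.

## Secondary-calibration dating

Relative node depths are mean path lengths: a node's height is the mean
of its path lengths to descendant tips, normalised by the root height,
with a parent-max adjustment guaranteeing monotonicity. Under a strict
clock this equals the true relative age exactly, which anchors the
closed-loop tests; under lognormal rate noise the averaging over tips
drives the error down (median ≈ 3–4 % at σ = 0.1 for 50-tip trees).
This is a deliberate, swappable stand-in for relative-rate frameworks
used by dedicated dating software; the module boundary (`relative_depths`
feeding `calibrate`) is where such an implementation would plug in.

Uniform calibrations are summarised by their midpoints. One constraint
fixes the global scale; several constraints fit the scale by least
squares over the constrained nodes, after which any calibrated node
outside its range is clamped to the nearest bound with its subtree
rescaled proportionally and parents raised minimally. Disjoint ranges on
one node, or clamps that cannot be reconciled, raise errors. The output
is ultrametric by construction and invariant to global rescaling of the
input branch lengths.

Jukes–Cantor distances use pairwise deletion (sites resolved in both
sequences), matching the per-column coverage filter's philosophy, and
refuse saturated pairs (p ≥ 0.75). Neighbor joining is delegated to
scikit-bio; negative NJ branches are clamped to zero with the deficit
pushed onto the child branches, preserving root-to-tip path lengths.
Rooting requires a declared outgroup (placed at the midpoint of its
terminal edge); outgroup choice is the caller's data decision.

## Equal-splits isolation

EI halves a lineage's inherited share at every split on the way to the
tips: `EI(tip) = Σ_e len(e) / 2^(number of splits between e's lower end
and the tip)`. On binary trees the statistic partitions total branch
length exactly (the conservation test holds to 1e-9 over random trees),
and EI(tip) ≥ pendant length always. Values are additionally reported
divided by the crown age, since trees dated on different calibration
schemes differ systematically in absolute scale. The implementation is
cross-checked against an independent path-enumeration oracle and against
the R package picante's equal-splits scores.

## Congruence regressions

Shared-node comparisons match nodes by shared-taxon-restricted clades
(the same convention as merging) and regress the paired MRCA ages by
ordinary least squares. Because axis order is a convention, both fits
(y on x and x on y) are carried in the result. Pendant-length
comparisons pair shared tips, optionally crown-scaled; the null tests
shuffle tip labels to produce genuinely independent pendant assignments.
Decile summaries (rather than histogram overlays) contrast two
normalised-EI distributions, with per-tip paired differences attached
when tip sets overlap.

## Constant-rate birth–death fit

The likelihood is the standard reconstructed-process density of the
branching times, conditioned on the crown age and on both crown lineages
surviving, with uniform sampling fraction ρ (species present in the tree
/ assumed extant total):

    p0(t) = 1 − ρr / (ρλ + (λ(1−ρ) − μ) e^{−rt}),     r = λ − μ
    p1(t) = ρ r² e^{−rt} / (ρλ + (λ(1−ρ) − μ) e^{−rt})²
    log L = log (n−1)! + 2[log p1(x₁) − log(1 − p0(x₁))]
            + Σ_{i≥2} [log λ + log p1(x_i)]

At μ = 0, ρ = 1 the maximiser reduces to the classical
(n−2)/total-branch-length Yule estimate, which the tests verify, and the
whole expression is checked against an independent numerical integration
of the p0/p1 ODEs to 1e-6. Optimisation runs Nelder–Mead in
(log λ, logit μ/λ) space with five seeded restarts; μ̂ estimates on pure-
birth data sit near the boundary and are reported as (near-)zero.

Masking the terminal artifact exploits the process' semigroup property:
the tree restricted to ages ≥ w is again a birth–death reconstruction
whose lineages at w are "sampled" with probability 1 − p0(w), so the
masked fit evaluates the same likelihood on shifted times with that
effective sampling fraction — exact, not ad hoc, though with fewer
events the variance grows. Episodic models, rate-shift detection and
Bayes-factor comparisons are out of scope; the in-repo question is
whether a constant rate describes the branching times, judged by the LTT
curve and the fit.

## Known limitations

* Mean-of-two age averaging is the simplest defensible reconciliation;
  published supertree pipelines use weighted multi-study schemes.
* Genus-base attachment ages are a documented convention, not an
  estimate.
* The cherry-only pruning rule means synthetic scenarios never exercise
  grafts whose recorded sister is a multi-tip clade; real literature
  evidence of that shape would attach at the clade's stem, which the
  sister-PL instruction format cannot express.
* Midpoint summaries of uniform calibrations discard range width;
  calibrated-node uncertainty is not propagated.
* The birth–death fit assumes uniform sampling; clade-biased missingness
  violates it.
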