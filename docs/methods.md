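# Methods

This note documents the models, algorithms, defaults and design decisions
behind `codonasr`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Sequence preparation

`filter_cds` applies its checks in a fixed order: (1) reject sequences
whose length is not a multiple of three, (2) reject sequences with a stop
codon before the final codon, (3) strip one terminal stop codon if present,
(4) apply the inclusive length window to the stop-stripped length.  The
order makes "internal stop" well defined (it presupposes an intact reading
frame) and makes the filter idempotent.  Nothing raises: every record ends
up either kept or rejected with one of three reasons, so a cohort can be
audited record by record.  The default window of 2,400–2,800 nt is the
full-length helper-NRC range; both bounds are parameters.

Codon threading replaces each aligned residue with its source codon and
each protein gap with `---`, so degapping any threaded row reproduces the
input CDS byte for byte — this invariant is enforced by the
`CodonAlignment` container and property-tested against simulated data.  A
residue that disagrees with its codon's translation is an error (naming the
residue index), not a warning: silent frame damage would corrupt every
downstream posterior.

Gappy-column trimming removes a column when its gap fraction strictly
exceeds the threshold g (default 0.9, i.e. a column survives at exactly 90%
gaps).  On codon alignments the unit of removal is the codon triple, judged
by its pooled gap fraction, because removing single nucleotide columns
would destroy the reading frame that codon posteriors depend on.  Trimming
that would remove every column is rejected loudly rather than returning an
empty alignment.

Deduplication is exact string equality after case normalisation, keeping
the first occurrence as representative; reverse-complement matching is
deliberately not performed (positive-strand coding sequences).  Manual
curation edits are expressed as patch records (sequence id, 1-based residue
position counted over non-gap characters, replacement) applied to the
protein alignment before threading, so they are reproducible inputs rather
than undocumented edits.

## Substitution models

Rate matrices are built as q_ij = s_ij π_j from symmetric exchangeabilities
s and stationary frequencies π, giving detailed balance by construction.
Named patterns: JC69 and K80 (equal frequencies), HKY85 (κ), TIM3 (the
restricted GTR with ties AC = CG and AT = GT), GTR, and the two-state JC2
used for gap presence/absence.  Zero exchangeabilities are rejected because
they break irreducibility.

Q is scaled so that the expected substitution rate at equilibrium equals 1,
and the rate-category mixture is rescaled so that
(1 − p_inv) · Σ wᵢ rᵢ = 1; branch lengths are therefore expected
substitutions per site averaged over the whole mixture, matching the
convention of standard ML phylogenetics software.  FreeRate-style
categories (e.g. R4) are accepted as explicit (rate, weight) pairs in the
model config; model *selection* is out of scope — the model family and its
parameters are inputs.

P(t) = exp(Qrt) is computed from the eigendecomposition of the
symmetrised matrix π^{1/2} Q π^{−1/2}; reversibility guarantees a real
spectrum, so the kernel is exact to machine precision (the JC69 diagonal
matches 1/4 + 3/4·e^{−4rt/3} to < 1e-12 over a grid of rt) with no
scaling-and-squaring error control needed.  Entries are clipped to [0, 1]
to remove −1e-17-style round-off.

## Likelihood and marginal reconstruction

The pruning pass is vectorised over sites and carries a per-site cumulative
log scaling factor per node, so partial likelihoods never underflow.  Gaps
and ambiguity codes (N/X) are missing data — a partial vector of ones —
because indel signal is handled by the dedicated binary reconstruction;
mixing the two in one model would double-count gaps.

Marginal (per-node) posteriors are used throughout, not joint
reconstruction: the experimental question is "what was the state at this
node, with what confidence", which is exactly the per-node marginal, and
per-state probabilities are what the ambiguity rule consumes.  For each
rate class the posterior is U·L normalised per node and site (U the upward
partial including the root prior, L the downward partial); classes are then
mixed with per-site class posteriors P(c | site).  The invariant class
contributes π_x restricted to states consistent with a constant site.
Posteriors are reported for internal nodes only.

Rooting: an outgroup, when declared, roots the tree on the outgroup's edge
at its midpoint (under reversibility the position along that edge does not
affect marginals elsewhere).  A multifurcating root with no declared
outgroup is accepted as the rooting point with a logged warning rather than
rejected — internal-node marginals are invariant to root placement for
reversible models, and star-tree inputs are legitimate.

Branch-length optimisation (used only when no externally estimated tree is
supplied) is coordinate ascent with a bounded scalar search per branch on
[1e-8, 10], accepting a proposal only if the total log-likelihood does not
decrease, sweeping until the improvement over a full sweep falls below
`tol`.  This is slow but monotone and dependency-free; on two taxa it
matches the closed-form JC distance −3/4·ln(1 − 4p̂/3) to < 1e-4.

## Indel reconstruction and codon combination

The alignment is recoded column-wise to "0" (non-gap) / "1" (gap) and
reconstructed under JC2 with the *input* branch lengths held fixed — the
lengths were estimated from nucleotide substitutions and re-fitting them to
binary gap data would conflate two different processes.

Codon posteriors are the product of the three nucleotide posteriors
(independence across positions within a codon is an approximation made by
the underlying site-independent model anyway).  Raw products and the
renormalised distribution are both retained for audit.  A codon site is
called a gap at a node when the mean gap posterior over its three columns
exceeds 0.5 — the MAP decision on the binary state; the threshold is a
parameter.  Residue posteriors sum renormalised codon posteriors over
synonymous codons of the standard code; stop-codon mass is reported
separately (and warned about above 5%) so that residues + gap + stop
conserve probability exactly.  Ancestral stop mass is expected: the
substitution model does not know about coding constraints, so some
posterior mass falls on stop codons even when no ancestor contained one.

Ambiguity is thresholded at the residue level (after synonymous summation),
because decisions about which ancestral protein variants to resurrect are
made per amino acid; codon-level tables are still emitted.  At each queried
position every state with p strictly greater than 0.3 (default) is a
candidate; if nothing clears the threshold the single MAP state is used
with a warning.  Variants are the Cartesian product of candidates ranked by
descending joint probability (ties broken lexicographically), truncated at
`max_variants` (default 16) with a warning, and labelled `anc<node>.<k>`
by rank.  Ranking by probability is the one deterministic, defensible
ordering; note that published variant numberings assigned by other criteria
(or arbitrarily) need not coincide with rank order — e.g. a historical
"variant .1" may be the *less* probable of two states.

## Interface contacts

Contacts are all heavy-atom pairs between the two chains with Euclidean
distance in [dmin, dmax], defaults 2.5–3.6 Å — the conventional
hydrogen-bond/salt-bridge window used by crystallographic contact listings.
Hydrogens are excluded (typically absent at moderate resolution anyway),
waters excluded by default, and only blank/'A' alternate locations are
kept.  A k-d tree accelerates the search; tests verify identity with the
all-pairs brute force.  Contacting receptor residues are merged into
regions while consecutive author-numbered indices differ by at most
`gap_tol` (default 15, chosen so that contact sets spanning the ranges
153–170 / 306–320 / 348–353 of an NRC1-type NB-ARC module cluster into
exactly three regions); region labels are interface1, interface2, … in
sequence order.

## Permutation statistics

The test statistic is the difference of group means of ordinal 0–7 HR
scores.  Labels are permuted without replacement, independently across B
resamples (default 10,000), and the two-sided p is
(#{|T*| ≥ |T_obs| − ε} + 1)/(B + 1) with ε = 1e-12 absorbing
floating-point ties; the +1 correction means p is never exactly 0.  The
exact-enumeration companion enumerates all C(n, n_A) assignments with
p = #{|T*| ≥ |T_obs|}/C(n, n_A) and serves as the oracle.

With heavily tied ordinal data this family of tests (ties counted as
extreme, as in standard library implementations) is mildly conservative:
under a null where both groups of 12 draw from the same 8-point score
distribution, the measured type-I error at α = 0.05 is ≈ 0.035–0.040
rather than 0.050.  This matches the reference scipy implementation under
identical conditions and is a property of discrete permutation nulls, not
of this implementation; the calibration experiment that measures it is part
of the validation suite, and its empirical rate sits essentially on the
lower edge of the binomial 99% band around the nominal level.

## Conservation matrices

Per column, frequencies are computed over non-gap canonical symbols with no
pseudocount; the information content is log₂|alphabet| − H and each symbol
contributes f·IC bits.  An all-gap column is undefined under a zero
pseudocount and is emitted as zeros with a warning.  No small-sample
correction is applied (consistent with the zero-pseudocount convention).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes: a
random bifurcating topology from uniform coalescent-style joins with i.i.d.
exponential branch lengths; codon sequences evolved by per-site
continuous-time simulation (exponential waiting times under Q, one rate
category drawn per nucleotide site and shared across the tree, invariant
sites at rate zero); and whole-codon presence/absence evolving under an
independent two-state chain, with the root fully present and all-ACGT.

Defaults, chosen once as a realistic regime for a plant NLR coding dataset:
HKY85 with κ = 2.0 and AT-rich frequencies (0.3, 0.2, 0.2, 0.3); four
free-rate categories (0.2, 0.6, 1.2, 2.0) at equal weights; indel gain/loss
rates (2.0, 0.2) per unit branch length, giving ≈ 9% equilibrium absence;
mean branch length 0.05 for the reference recovery experiment.

Two deliberate idealisation choices:

- **Stop avoidance by thinning.**  A proposed substitution that would
  create an in-frame stop codon is discarded while time still advances
  (a thinned/conditioned CTMC).  This mimics the purifying selection that
  keeps real CDS frame-clean and — unlike rejection-sampling whole
  lineages — remains well behaved at the 16-fold branch-length scalings
  used in the degradation experiments, where nearly every unconstrained
  lineage would otherwise acquire a stop.  The cost is a slight departure
  from the nominal equilibrium composition at very long branches, which the
  stationarity test accounts for.
- **Hidden sequence under gaps.**  Nucleotide evolution continues at absent
  codons (masked by gaps in the emitted rows), so a codon regained later
  has a defined sequence.  Presence/absence and substitution are therefore
  exactly independent processes, matching the separation the reconstruction
  assumes.

What passing tests show — and do not.  Recovery experiments score MAP
ancestral states against recorded truth under a *matched* model, i.e. they
measure the method's statistical efficiency, not robustness to model
misspecification.  Real NRC data add alignment error, recombination,
lineage-specific composition and selection, none of which the generator
emulates; accuracy numbers from these tests are upper bounds for real data.
Under the reference regime (32 taxa, 300 codons, mean branch 0.05) MAP root
residues match truth at roughly 85–100% of sites depending on the realised
tree (≈ 96% at the fixed regression seed), with mismatches concentrated at
sites whose true state carries posterior ≈ 0.3 — i.e. at honestly
uncertain sites; accuracy degrades monotonically at 4× and 16× branch
scaling, and presence/absence recovery stays near-perfect until divergence
is extreme.

## Numerical choices

- Per-site log-scale tracking in both pruning directions; posterior
  normalisation cancels scales exactly, and category mixing happens via a
  per-site log-sum-exp.
- Marginal/indel posteriors agree with the exhaustive-enumeration oracle to
  < 1e-10 on hundreds of random ≤ 5-leaf instances (the validation suite
  recomputes this).
- MAP ties (vanishingly rare with continuous posteriors) break by state
  order; variant ordering ties break lexicographically.
- Degenerate inputs: empty sequences, duplicate ids, non-simplex
  frequencies, negative branch lengths, frame-breaking gaps and
  out-of-range reference positions all fail fast with specific messages.

## Validation problem sizes

The validation suite (shared by the tests and `scripts/acceptance.py`) uses
200 random ≤ 5-leaf/20-site instances for the oracle comparison, 6-leaf
trees for re-rooting, 600 sites for the two-taxon MLE, 32 taxa × 300 codons
for the recovery experiments, 10,000 resamples for Monte-Carlo/exact
agreement and 2,000 null datasets (B = 999, 12 per group) for type-I
calibration — sizes chosen so the whole battery completes in well under a
minute on one CPU while leaving sampling error far below the tolerances
being checked.

## Known limitations

- No topology search, model selection or bootstrap support: tree and model
  are inputs, as in the intended workflow.
- Codon posteriors assume within-codon independence given the site model;
  a true codon model (e.g. with dN/dS) is out of scope.
- The gap/character separation treats gaps as missing for nucleotides; at
  sites where most leaves are gapped, nucleotide posteriors revert towards
  the prior and variant calls there lean on the indel reconstruction.
- Branch-length optimisation recomputes the full likelihood per proposal;
  it is intended for small fixtures, not thousand-taxon trees.
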