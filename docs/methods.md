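# Methods

This note documents the models, algorithms and numerical choices behind
`netadmix`, and what the package's validation experiments do and do not
establish.

## Scope and data model

The package analyses historical introgression among closely related taxa
from three kinds of evidence: per-locus gene trees (newick, possibly with
unequal taxon sets), rooted level-1 phylogenetic networks with inheritance
probabilities γ (extended newick with `#H` hybrid tags and
`:length:support:gamma` fields), and matrices of biallelic SNP genotypes
(a documented TSV dialect, or VCF). A network with h hybrid nodes displays
2^h trees, each obtained by keeping one parent edge per hybrid node and
suppressing the resulting degree-2 nodes; the probability of a displayed
tree is the product of the chosen γ values. Throughout the package,
network-level quantities are expectations over this displayed-tree
mixture:

- pairwise leaf distance: d(i,j) = Σ_T p_T · d_T(i,j) (patristic in each
  displayed tree). This definition reduces to the plain patristic matrix
  for trees and makes distances, scoring and calibration mutually
  consistent.
- expected quartet concordance factors (below);
- discrete-trait likelihoods (below).

## Coalescent simulator

Gene trees are simulated backward in time under the multispecies
coalescent on the network: within an edge, k lineages coalesce at rate
k(k−1)/2 per coalescent unit; at a hybrid node each lineage independently
follows a parent edge with probability γ; above the root coalescence runs
to a single lineage. The network must be *time-consistent* (every node
has a well-defined age, leaves at age zero); nodes are processed in age
order with a reverse-topological tie-break so that zero-length
(instantaneous-admixture) hybrid edges are handled exactly. Simulated
trees are ultrametric in coalescent units; among-locus rate variation is
emulated by an i.i.d. lognormal multiplier per locus (median 1, log-sd
`rate_sigma`), which is precisely the nuisance the QC normalisation
removes. Missing taxa are dropped i.i.d. per locus with probability
`m_tax` before simulation.

SNPs follow an infinite-sites scheme: per locus, mutations are placed on
genealogy branches with probability proportional to branch length; tips
below the branch carry the derived allele. Genotypes are haploid 0/1 by
default — matching a one-individual-per-taxon design — with an optional
diploid mode (two sampled lineages, 0/1/2 genotypes) for flagged taxa.
Positions are uniform within a locus of `locus_length` bp, and genotypes
are masked at rate `m_gt`. Although a single segregating site per locus
is the canonical setting, `snps_per_locus > 1` places several independent
mutations on the same genealogy so that thinning and one-SNP-per-locus
selection have realistic input.

Randomness contract: one root seed; the stream of locus i is derived as
`default_rng([seed, i, stage])`, so any locus is reproducible
independently of the number of loci, and identical configurations give
byte-identical outputs.

Defaults mirror the shape of the target study system: 18 taxa (17
ingroup in two clades plus one outgroup), 964 loci, `rate_sigma` 0.5,
`m_tax` 0.05, `m_gt` 0.05, and two reticulations with γ ≈ 0.25 and 0.33
(`netadmix.datasets.study_network`). The built-in taxa, grouping and
trait tables are synthetic stand-ins for validation; real analyses take
these as user configuration.

What the simulator does *not* emulate: finite-sites sequence evolution,
recombination within loci, gene-tree estimation error, alignment or
paralogy artefacts. Tests passing on simulated data therefore validate
the statistical machinery downstream of tree/SNP inference, not
robustness to upstream inference error.

## Gene-tree quality control

Two filters, both in tip-to-tip patristic distances (rooting-free):
(1) max ingroup distance ≤ 1.5 × max ingroup–outgroup distance, and
(2) min ingroup–outgroup distance ≥ 1e-4. Boundaries are inclusive
(literal reading of "not exceed" and "≥"). Trees lacking the outgroup or
with fewer than two ingroup tips are excluded, not errors. Filtering
precedes normalisation; passing trees are divided by their mean
outgroup–ingroup distance, making that mean exactly 1 (idempotent,
ratio-preserving). The ratio filter is scale-invariant; only the 1e-4
floor is scale-sensitive.

## Topology weighting and the ILS test

For four taxon groups, weights of the three unrooted quartet topologies
are computed by exact enumeration over all combinations of one tip per
group; an unresolved (polytomous) combination splits its vote equally. A
seeded sampling fallback engages above 10^6 combinations (not reached at
this package's group sizes). Trees missing a whole group are unusable and
excluded — the "unequal taxon sets" handling. Majority rule converts
weights to support (ties split; support values are restricted to
{0, 1/3, 1/2, 1}); support sums are rounded to the nearest integer pair
preserving their total before the test (flagged when rounding changed
anything). The ILS null — minor and contradictory topologies equally
frequent — is tested with a 1-df chi-square; the reported p-value is the
two-sided upper tail, with the signed minor-minus-contradictory direction
reported alongside so a one-sided reading remains available.

## Site-pattern statistics

Patterson's D and the f4-ratio use the standard allele-frequency forms
(see module docstring); significance comes from an m-block jackknife over
sites (default 20 equal blocks; configurable) with two-sided normal
p-values. The f-branch statistic follows the median-of-minima definition
of the tool it mirrors, with negative contributing f4-ratios floored at
zero; per-cell p-values are obtained by jackknifing the whole statistic,
and Benjamini–Hochberg adjustment runs across all defined cells. SNP
filtering drops sites at ≥ the missing-data cutoff (strict "<20%"
reading) and thins greedily from the lowest position, keeping a site only
when ≥ `thin_bp` from the last kept site on the same locus. The
f4-ratio approximates the admixture fraction best when the donor's
private drift since the gene flow is small relative to the donor taxon's
total private drift; the validation experiment uses deep splits and
recent gene flow, which is the regime the estimator was designed for, and
recovers γ ∈ {0.1, 0.3, 0.5} within ±0.07 at 5 000 loci.

## Network scoring and selection

Expected quartet CFs on a tree with quartet-internal branch t are
(1 − (2/3)e^{−t}, (1/3)e^{−t}, (1/3)e^{−t}); on a network they are the
γ-weighted mixture over displayed trees. The mixture is exact when, for a
given quartet, at most one lineage can enter each reticulation (e.g.
terminal-lineage introgression); otherwise it is an approximation — the
simulator quantifies the error for any configuration of interest, and
the validation networks are in the exact regime. Candidate networks are
scored with a multinomial composite log-likelihood
Σ_q n_q Σ_topologies obsCF·log(expCF) (expected CFs floored at 1e-12),
whose differences are natural-log units comparable to the published
thresholds: Δ ≤ 10 strong, ≤ 20 moderate, < 30 poor, ≥ 30 excluded
(boundaries to the better class). Candidates whose reticulation involves
the outgroup (outgroup below a hybrid node, or the outgroup stem inside a
reticulation cycle) are excluded a priori. The prevailing topology is
chosen by majority rule over resamplings: among reticulation counts
where some topology is strong-or-moderate in a majority of resamplings,
take the highest count; within it return every topology supported in at
least two resamplings, ordered by supporting resamplings then mean score.
Network *search* is out of scope — candidates are supplied (e.g. the
rotation set of an external search) and only scored and ranked here. On
18 taxa the observed-CF table can be restricted to a seeded subsample of
quartets (`max_quartets`, pipeline default 300 of the 3 060) to keep
desk-scale runs fast; scoring is linear in quartets, so ranking is
unaffected in expectation.

## Calibration

Node ages (leaves at zero) parameterise the network, making
ultrametricity and hybrid-below-parent constraints structural. On an
ultrametric network d(i,j) = Σ_T p_T · 2·age(mrca_T(i,j)), linear in the
age vector, and internal branch lengths are age differences — so for a
fixed exponent p the objective

    F(ages, p) = Σ_{i<j} [d_net(i,j) − D̄(i,j)^p]²
               + w Σ_{internal e} [l_e − l⁰_e]²

is a linear least squares, solved in closed form and refined with
constrained optimisation (multistart SLSQP) only when the unconstrained
solution violates an age ordering. The penalty weight defaults to
w = mean(off-diagonal D̄) / mean(initial internal branch length), computed
once from the inputs; terminal branches are unpenalised, since computing
them is the point of the procedure. The exponent is optimised by bounded
1-D search over [p_init/10, 10·p_init] on a log scale, with the identity
p = p_init evaluated explicitly as a guard against local optima. D̄ is
the mean patristic distance over (normalised) gene trees containing both
taxa of a pair; pairs never co-present are an error unless explicitly
masked. Perfect-data inputs are recovered to machine precision, and
squared-distance inputs recover p = 0.5.

## Discrete-trait ancestral reconstruction

The equal-rates model (the k-state Mk chain; single rate α, uniform
stationary distribution) supplies transition probabilities in closed
form. Network likelihood is the displayed-tree mixture
Σ_T p_T · L_T(α), each L_T by Felsenstein pruning with a uniform root
prior. α is fitted by bounded 1-D search on log α ∈ [1e-8, 1e3]
(boundary hits flagged; a constant character pins α at the lower bound).
`fit_ersm` accepts several characters and fits α jointly by summed
log-likelihood — single binary characters barely constrain a rate, so
the recovery experiment (200 characters, true α = 1 on a depth-1
network) uses the joint fit. Marginal posteriors are computed per
displayed tree by the standard up-down pass and mixed with weights
p_T·L_T/L; a node suppressed in a displayed tree inherits the posterior
of its surviving edge's child, and a node absent from some displayed
trees is averaged over the trees containing it (weights renormalised).
State spaces need k ≥ 2; when all tips share a state the caller must
name the state space explicitly. Traits are modelled independently; no
correlated-evolution testing is attempted.

## Pipeline

A YAML config drives the stages simulate → qc → twisst → sitestats →
netscore → calibrate → asr. Each stage writes machine-readable tables
and a `.done` marker into its own subdirectory; re-running resumes after
completed stages; a preflight check fails before anything runs if a
required input file is absent. All floats are serialised with a fixed
format and no timestamps enter outputs, so identical config + seed gives
byte-identical runs.

## Validation protocol and problem sizes

The heavy checks live in `tests/test_acceptance.py` and are recomputed
from scratch by `scripts/acceptance.py`: 20 000 loci for closed-form CF
checks (±0.01); 500 × 1 000 loci for the ILS-test type-I rate (nominal
0.05, accepted in [0.03, 0.07]) and 100 × 2 000 loci for power (≥ 0.9 at
γ = 0.3); 50 replicates × 2 000 loci per γ for CF-based γ recovery
(±0.05 in ≥ 90%); 5 000 loci for f4 recovery (±0.07); 50 × 800 loci for
f-branch null FDR (≤ 0.05); 100 random trees for calibration fixed
points (< 1e-10); 200 characters for α recovery (±20%); and the full
18-taxon, 964-locus pipeline run twice for byte-level reproducibility.
These sizes were chosen so each check's Monte-Carlo error is comfortably
below its tolerance while the whole protocol stays desk-scale.

## Known limitations

- The displayed-tree CF mixture is not the full network coalescent; for
  reticulations deep inside the tree with several entering lineages it
  deviates, and scoring accuracy there should be checked against the
  simulator before trusting fine Δ distinctions.
- f-branch p-values inherit the block-jackknife normal approximation;
  with few informative sites per cell the q-values are conservative but
  approximate.
- Calibration ages are relative (no absolute time calibration), and the
  exponent search assumes a single global power transform.
- The simulator's idealisations (no gene-tree error, free recombination
  between loci, none within) mean empirical data can violate assumptions
  in ways these tests do not probe.
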