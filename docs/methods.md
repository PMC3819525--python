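# Methods

## The problem

A genotype–phenotype (GP) map over N biallelic diploid loci assigns a
genotypic value G(g) — the mean trait value — to each of the 3^N genotypes.
Counting the number of "2" alleles per locus (0, 1 or 2) induces the product
partial order on genotype space: within any fixed genetic background,
11 < 12 < 22 at every locus. A map is *monotone (order-preserving) with
respect to locus k* when G never decreases along that chain in any
background; non-strict inequalities keep complete dominance and complete
magnitude epistasis inside the monotone class. Monotonicity is a functional
property of the map itself, independent of allele frequencies, and it is
the structural feature behind high additive variance fractions at
intermediate allele frequencies. `gpmono` quantifies it two ways and asks,
mechanistically, which gene-regulatory architectures produce it.

All maps use one canonical storage order: base-3 encoding of per-locus
2-allele counts with locus 1 most significant (1111, 1112, 1122, 1211, …,
2222). An allele-orientation convention fixes the remaining label freedom:
alleles are swapped per locus so the all-1 homozygote carries the smallest
of the 2^N fully homozygous values. Orientation ties (equal homozygote
values) are broken by fewest flips, then lexicographically smallest flip
pattern; this is a convention of this package, chosen so orientation is a
deterministic idempotent operation.

## Measure 1: degree of monotonicity from substitution effects

For locus k and background g^(k), the two single-allele substitution
effects are s² = G(·12·) − G(·11·) and s¹ = G(·22·) − G(·12·); over all
backgrounds there are 2·3^(N−1) of them. With P_k the sum of positive
effects and N_k the summed magnitude of negative effects, T_k = P_k + N_k,

    m_k = |P_k − N_k| / T_k,      m = Σ_k m_k T_k / Σ_k T_k.

m_k = 1 iff all nonzero effects at locus k share one sign; m_k = 0 when
positive and negative effects balance exactly. Both m_k and m are invariant
to allele relabelling (the absolute value in the numerator) and to positive
affine rescaling of the trait. The T_k weighting makes loci with large
total substitution effects dominate m, so a monotone major locus masks
order-breaking minor loci — intended behaviour, since m targets the map's
overall transmission behaviour.

Numerical zero handling: effects with |s| ≤ `zero_tol` are excluded from
both sign sets (the sign sets are defined by strict inequalities). The
default `zero_tol` is 1e-9 × (max − min of the genotypic values), scaled so
that equilibria computed by an ODE solver are not declared order-breaking
by round-off. A locus with T_k = 0 carries no variation; it is excluded
from the weighted mean, and a fully flat map has undefined m (reported as
NaN with a flag, never an exception).

The boolean order-breaking flags evaluate the monotonicity definition
after orientation. A corner case follows from the convention: when
homozygote values tie, the fewest-flips tie-break can select an orientation
under which a locus's nonzero effects are all *negative*; such a locus has
m_k = 1 (one-signed gene action) but a raised flag. The measures m_k and m
are unaffected; analyses that need per-locus flags for uniformly decreasing
loci should inspect the sign of P_k − N_k.

## Measure 2: isotonic regression and R²_mono

The monotone component G_M of a map G is the least-squares projection of G
onto the closed convex cone of maps satisfying every cover-edge constraint
of the partial order (2N·3^(N−1) constraints). Convexity makes G_M unique.
The residual G_N = G − G_M satisfies Σ_g G_M(g)·G_N(g) = 0 and
Σ_g G_N(g) = 0, so var(G) = var(G_M) + var(G_N) and

    R²_mono = var(G_M) / var(G)

is the fraction of the map's variance a fully order-preserving map can
carry. R²_mono = 1 iff G is monotone; it stays strictly positive even for
purely overdominant or purely epistatic maps, because the nearest monotone
map is never flat-at-the-mean for such inputs. Unlike m, R²_mono is *not*
invariant to allele relabelling, so orientation is applied by default
before fitting (a flag disables it). Variances use the population
convention (divisor 3^N); the ratio is divisor-invariant.

Algorithm: the projection is computed exactly through Moreau's
decomposition. With C the (edges × genotypes) difference matrix, the cone
is K = {x : Cx ≥ 0} and proj_K(g) = g + Cᵀλ*, where λ* solves the
nonnegative least-squares problem min_{λ≥0} ‖g + Cᵀλ‖². That dual is
solved by a classical Lawson–Hanson active-set iteration implemented in
the package (finite, deterministic, exact to least-squares round-off).
The input is centred and scaled to unit max-magnitude first; this is exact,
not approximate, because the constant vector lies in the cone's lineality
space and the cone is invariant under positive scaling, and it keeps the
active-set solve well conditioned. A graph-PAV block-merging scheme would
also work; the dual projection was chosen because its optimality is
directly certifiable (feasibility plus complementary slackness) and its
correctness is vetted in the tests against an independent generic
constrained quadratic solver (SLSQP) on hundreds of random maps, with
objective agreement to ≤1e-6. Degenerate level-set ties are moot for
outputs: the fitted values are unique. Feasibility violations above the
solver tolerance (default 1e-10) raise rather than propagate.

## Variance decomposition under equal genotype frequencies

With all genotype frequencies equal to 1/3^N, the statistical and
functional network-of-interacting-alleles (NOIA) formulations and the
unweighted regression model coincide, and the genetic variance is simply
the variance of the 3^N genotypic values. The package regresses G on the
fully orthogonal basis formed by Kronecker products (locus 1 most
significant) of the per-locus contrasts

    mean (1, 1, 1),  additive (−1, 0, 1),  dominance (−1, 2, −1),

indexed by 2-allele content. Because the basis is orthogonal and full
rank, the fit is exact: summing all components reconstructs G, each
non-mean term contributes var_j = β_j²·var(column), the term variances sum
to V_G, and V_A is the sum over single-locus additive terms. Contrast
scaling is immaterial — component variances are projection variances.
V_A/V_G is reported (NaN for flat maps) along with per-term variances and
aggregates by interaction order. Arbitrary genotype frequencies, linkage
disequilibrium and change-of-reference operations are out of scope.

## Gene regulatory network model

Three diploid genes are wired by a signed 3×3 connectivity matrix A with
entries in {−1, 0, 1} and at most two regulators per gene. Each allele
copy i of gene k follows the sigmoid ODE

    dx_ki/dt = α_ki · R_ki(y₁, y₂, y₃) − γ_ki · x_ki,   y_k = x_k1 + x_k2,

with Hill regulation S(y, θ, p) = y^p/(y^p + θ^p) per activator (1 − S per
repressor), the product of two regulators' terms (Boolean AND), and
R_ki = 1 for unregulated genes. θ is the half-maximal regulator dose
(concentration units), p the dimensionless steepness. The phenotype of a
genotype is the equilibrium y₃. The Hill term is evaluated in log-ratio
form so extreme doses or steepnesses cannot overflow.

Parameters and sampling ranges (per Monte-Carlo replicate): α ~ U(100, 200)
per gene per allele; γ = 10 for every copy; θ ~ U(20, 40) and p ~ U(1, 10)
per gene–regulator pair. Without pleiotropy, genotypic variation enters
only through α: θ and p are drawn once per gene–regulator pair per
replicate and shared by both alleles. With pleiotropy, each allele carries
its own α, θ and p. Heterozygotes express one copy of each allelic
variant; homozygotes express two copies of one variant, making the 11/22
phenotypes exchangeable under allele-table swaps.

Steady states: integration starts from the all-zero state (a fixed
convention; for multistationary systems it selects one attractor
consistently and is recorded as part of the protocol). The system is
integrated with a stiff-capable solver (LSODA, rtol 1e-8, atol 1e-10) in
windows of 10 time units up to t = 1000 — the intrinsic time constant is
1/γ = 0.1, so this allows four orders of magnitude of slack. Convergence
requires both the relative state change across a window and the relative
right-hand-side residual to fall below 1e-6. A converged state is then
polished by a Newton-type root solve and accepted only if the residual
drops below 1e-9 (relative), the state is nonnegative, and the root stays
near the integrated state; this makes the recorded phenotype accurate to
~1e-12 relative, far below the monotonicity zero-tolerance, so solver
noise cannot masquerade as order-breaking. Everything else — including
sustained oscillation, which never satisfies the window criterion — is a
non-convergence discard, never an exception inside the Monte-Carlo loop.

Replicate filtering: a genotype set where any of the 27 genotypes fails to
converge is discarded; a converged map is discarded as *flat* unless its
absolute range (max − min) and relative range (absolute range / mean) both
exceed 0.01. Phenotypes are nonnegative so the mean is safe as the
denominator.

## Motif space

With ≤2 regulators per gene there are 19 sign patterns per row, hence
19³ = 6859 connectivity matrices. Requiring X₃ downstream of both X₁ and
X₂ — directly (A₃₁A₃₂ ≠ 0) or one direct and one indirect (A₃₁A₁₂ ≠ 0 or
A₃₂A₂₁ ≠ 0) — leaves 3724; each clause already links all three genes, so
weak connectivity is implied (asserted in tests, not separately filtered).
Collapsing the X₁↔X₂ relabelling symmetry (38 matrices are
swap-invariant; 3724 = 2·1881 − 38) leaves 1881 representatives, each the
lexicographically smallest flattening in its orbit. Loop products read the
regulatory structure off A: autoregulation FLₖ = Aₖₖ, two-gene loops
FL₁₂ = A₂₁A₁₂ (etc.), three-gene loops FL₁₂₃ = A₃₂A₂₁A₁₃ and
FL₂₁₃ = A₃₁A₁₂A₂₃, and feedforward products FFL₃₂ = A₃₂(A₃₁A₁₂),
FFL₃₁ = A₃₁(A₃₂A₂₁). A motif is classified by two booleans: *incoherent
feedforward present* (either FFL product negative) and *positive feedback
present* (any FL product positive — positive autoregulation counts; the
exact four-way class counts 287/48/1294/252 confirm this reading).
Classification commutes with the X₁↔X₂ swap, so the representative choice
cannot change class counts.

## Monte-Carlo study protocol and scaling

The full-scale study design is 1000 replicates for each of the 1881 motifs
with a motif kept for analysis only if ≥100 replicates are usable. That
scale is a cluster-sized computation; the package therefore exposes the
replicate count as configuration and scales the inclusion threshold
proportionally (100 per 1000 replicates, minimum 1), recording the scaled
threshold in the output. The bundled acceptance checks run 20 motifs × 50
replicates of the class lacking both incoherent feedforward and positive
feedback without pleiotropy — chosen because that class has a sharp,
scale-free prediction: monotone gene regulation without those two motifs
cannot produce order-breaking maps, so *every* usable map must have m = 1.
This the simulation reproduces exactly. Aggregate discard counts at full
scale depend on integrator settings and the initial-state convention and
are not reproduced quantities.

Randomness: one root seed; each (motif, replicate) pair gets its own
deterministic child stream (seed-sequence spawn keys), so any subset of
the study reproduces the full study's values exactly.

## What the synthetic inputs do and do not show

Random GP maps draw 3^N genotypic values i.i.d. uniform; they probe the
measures' behaviour across map space, not the distribution of real maps
(real maps are far more monotone than uniform ones — that is the point of
the GRN study). The monotone-rearrangement variant sorts the three values
within every background of one locus, the simplest operation guaranteeing
order-preservation for that locus while preserving the value multiset.
The catalog of classical two-locus maps uses values normalised to [0, 1]
except the mouse body-weight map, which uses its published gram-scale
values; both measures and V_A/V_G are scale-free, so normalisation is
harmless. GRN-derived maps inherit every idealisation of the model:
equilibrium phenotypes, AND-gate regulation, ≤2 regulators, no molecular
noise, no environmental variance. Passing tests demonstrate the measures'
mathematical properties and the architecture–monotonicity link inside this
model family, not field performance on measured phenotypes.

## Known limitations

- Genotype spaces are complete 3^N tables: no missing genotypic values,
  no more than two alleles per locus.
- The isotonic solve builds a dense cover matrix; fine through N = 4–5,
  not intended for large N.
- m is undefined (NaN) for flat maps and loci without variation, by
  design; downstream code must tolerate NaN.
- Non-convergence discards cannot distinguish oscillation from
  slow transients longer than t = 1000 (≈10⁴ intrinsic time constants).
- The orientation tie-break interacts with the order-breaking flags as
  described above; m and R²_mono are unaffected.
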