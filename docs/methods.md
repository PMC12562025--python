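# Methods

## The model

All computation assumes a balanced completely randomized design: G
genotypes (mother plants), T traits, r replicates per genotype and trait,

    y_ijt = mu_t + g_it + e_ijt,

with genotypic effects g_i ~ MVN(0, D C D) (D = diag(sigma_g,t), C an
optional cross-trait correlation of genotypic effects) and residuals
e_ijt ~ N(0, sigma_e2,t), independent across replicates and traits.  Under
this model the one-way expected mean squares are E[QMg] = sigma_e2 +
r*sigma_g2 and E[QMr] = sigma_e2, which the moment estimators invert.
There is no genotype × environment term and no spatial structure: the
whole cohort is one experiment.

## Estimators and conventions

Per trait, with k = r replicates and grand mean m:

- sigma_f2 = QMg/k, sigma_e2 = QMr/k, sigma_g2 = (QMg − QMr)/k.
- h2 = sigma_g2/sigma_f2 = 1 − QMr/QMg: the broad-sense heritability of
  genotype MEANS (its population value is sigma_g2/(sigma_g2+sigma_e2/r)),
  stored as a fraction and rendered ×100 in exports.
- CVg = 100*sqrt(sigma_g2)/m; **CVe = 100*sqrt(QMr)/m**, i.e. the residual
  sd on the observation scale, not sqrt(QMr/k).  This asymmetric
  convention is deliberate: it makes CVe identical to the experiment's
  ordinary CV%, and it is the convention under which published tables
  that print sigma-based definitions alongside CVg/CVe and CV% are
  numerically self-consistent (the ratio then equals
  sqrt((QMg−QMr)/(k*QMr))).
- Negative sigma_g2 (QMr > QMg) is reported as-is with a
  `negative_sigma_g2` flag — never truncated to zero — so simulation
  studies observe the raw estimator; CVg and the ratio are NaN in that
  case.  QMr = 0 flags an infinite ratio; m = 0 flags undefined CVs.
- The h2 estimator has a small negative bias of order (1−h2)*2/(G−3)
  (from E[1/QMg]); at G = 160 this is under 0.01 for any h2 ≥ 0.3.

Seed-vigor indices are computed per replicate from daily emergence counts
and then treated as ordinary traits: ESI = sum n_i/t_i (seedlings/day,
zero when nothing emerged; day 0 is rejected) and MET = sum n_i t_i /
sum n_i (days; undefined without emergence).

## Scott–Knott

At a node holding k mean-ordered genotype means, the split maximizing the
between-group sum of squares B0 over all k−1 contiguous cuts is tested
with lambda = pi/(2(pi−2)) * B0/sigma0^2, where sigma0^2 =
(sum (ybar_i − ybar)^2 + nu*s2_ybar)/(k + nu), s2_ybar = QMr/r, and nu =
G(r−1) is the residual df of the trait's own ANOVA (nu and s2_ybar are
global: deeper recursion reuses them, as in the classical procedure).
The split is accepted when lambda exceeds the continuous chi-square
quantile at level alpha with k/(pi−2) (non-integer) df; recursion stops
otherwise.  Ties in B0 go to the leftmost cut for determinism.  Classes
are contiguous by construction and labelled a, b, c, … by descending
class mean.  Consequences worth knowing: the number of groups is
non-decreasing in alpha, and as QMr → 0 every distinct mean eventually
becomes its own group (significance is relative to the noise floor).

## Divergence

The pooled residual covariance Psi[t,u] = sum_ij (y_ijt − ybar_it)(y_iju −
ybar_iu) / (G(r−1)) has each trait's QMr on the diagonal.  D2 between
genotype mean vectors uses Psi on the observation scale by default; the
`means` scale (Psi/r) multiplies every D2 by the constant r and changes
no grouping, only absolute fusion levels — published absolute cutoffs are
therefore only comparable within one convention.  Distances are computed
by Cholesky whitening (solve, never an explicit inverse in the distance
loop); a condition number above 1e12 warns, exact singularity (collinear
traits, or pooling df < T) raises with advice to drop traits.

Singh's per-pair trait terms c_j = d_j (Psi^{-1} d)_j are kept signed
(negative terms are possible with correlated traits) because
sum_j c_j = D2 holds exactly only for the signed decomposition; S_j sums
the signed terms over all unordered pairs, computed in closed form via
sum_pairs d d' = G * sum_i (m_i − mbar)(m_i − mbar)'.

## Clustering

UPGMA fusion level = the average inter-cluster dissimilarity itself (not
halved), so Newick branch lengths are parent level − child level and a
leaf's root distance equals the final fusion level.  Agglomeration is
delegated to scipy's average-linkage implementation; merge heights equal
the textbook O(G^3) algorithm (the test suite carries one as an oracle),
and the merge order on exact ties follows scipy's deterministic
nearest-neighbor-chain convention — tie order can differ from a
lexicographic rule but no reported quantity (heights, cophenetic
distances, cutoff, groups) depends on it for real-valued input.
Cophenetic correlation is the Pearson correlation of the G(G−1)/2
original dissimilarities with the fusion levels at which pairs first
join (needs G ≥ 3).  The Mojena cutoff is mean(alpha_m) + k*sd(alpha_m)
with the SAMPLE standard deviation over the G−1 fusion levels; k defaults
to 1.25, a widely used recommendation, and is a CLI flag.  Cutting severs
merges with level ≥ cutoff (strict "below survives" rule), so a cutoff of
0 gives all singletons and +inf one group; group ids are numbered by
first leaf appearance.

## Synthetic cohorts: what they do and do not show

`simulate_cohort` draws exactly the model above: multivariate-normal
genotypic effects, independent normal residuals, mandatory integer seed,
byte-identical CSV export per seed.  Defaults in examples mirror a
realistic trial scale (G = 160, r = 4 for recovery studies; tests use
smaller G for speed).  Passing recovery tests therefore demonstrates that
the estimators invert the model they assume — not that real data meet the
assumptions: the generator has no non-normal errors, no variance
heterogeneity between genotypes, no genotype × environment interaction,
no spatial field trends, and percentage traits are simulated as plain
normals rather than bounded binomial fractions (arcsine-type transforms
are intentionally not applied anywhere).

## Replay mode and the bundled published summary

`phenodiv replay` applies the estimator formulas to a published ANOVA
summary (trait, QMg, QMr, mean; k supplied), enabling desk-scale checks
when raw data are unavailable.  The bundled summary of a 160-mother-plant
*Hymenaea martiana* trial (18 traits, k = 4) carries two columns flagged
`inconsistent` whose printed h2/CVg–CVe cannot be reconciled with their
own printed mean squares (shoot dry mass, emergence speed index) — they
are retained for completeness but excluded from validation, as are CV%
checks for the two emergence percentages, whose printed integer-scale
means are too coarse to reproduce a 2-decimal CV%.

## Numerical choices and problem sizes

- Validation rejects (never imputes) unbalanced or missing cells; all
  formulas assume equal replication.
- Long CSV (`genotype,replicate,trait,value`) is canonical; wide is an
  importer.  Trait values stay in original units (D2 is scale-invariant).
- Acceptance-style checks run at: 100 cohorts of G=160×r=4 for recovery
  (means of h2 within ±0.02, sigma_g2 within 5%), 1000 null traits at
  G=30×r=4 for the 5% type-I rate, exhaustive Scott–Knott oracles at
  G ≤ 8, naive UPGMA oracles at G ≤ 10 — sizes chosen so the whole suite
  completes in seconds while keeping Monte-Carlo standard errors well
  inside the asserted tolerances.
- Fixed seeds throughout (SeedSequence-derived in tests, `--seed` in the
  acceptance script); the h2-recovery check at true h2 = 0.3 is the
  tightest: estimator bias ≈ −0.009 plus a 100-seed standard error of
  ≈ 0.009 against a ±0.02 band.
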