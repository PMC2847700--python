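# Methods

This note documents the statistical model behind the package, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## The problem

Skeletal-muscle insulin resistance in type 2 diabetes presents a puzzle:
the coding mRNA transcriptome of patient muscle is essentially invariant,
yet roughly a third of the muscle-expressed miRNAs shift in disease, many
already in impaired glucose tolerance. Because miRNAs act largely by
blocking translation, their collective effect should surface at the
protein level without any mRNA signature. When ~60 miRNAs move at once —
some up, some down, many sharing targets — single miRNA–target pairs say
little; what matters is the net, direction-aware targeting pressure on
each gene. The wCCS ranking quantifies exactly that.

## Scoring model

Every conserved 3'UTR target site carries a context score `c ≤ 0` (the
TargetScan convention: more negative = stronger predicted repression).
For a gene *g* with site set *S(g)* over the disease-modulated miRNAs:

* **CCS** (cumulative context score):
  `CCS(g) = Σ_{s∈S(g)} c_s`
* **wCCS** (weighted CCS), with `w_m` the linear fold-change magnitude
  (≥ 1) of miRNA *m* in disease:
  `wCCS↑(g) = Σ_{s∈S(g), m(s) up} c_s · w_{m(s)}`,
  `wCCS↓(g) = Σ_{s∈S(g), m(s) down} c_s · w_{m(s)}`

Only sites whose gene is tissue-expressed (present/marginal detection on
at least one chip) and whose miRNA passed differential calling enter the
computation. The two directional distributions are quartiled
independently over the genes with at least one site in that direction;
Q1 (most negative 25%) of wCCS↓ is the candidate *protein-up*
(de-repressed) list, Q1 of wCCS↑ the candidate *protein-down* list.

**Overlap resolution.** A gene in both Q1 lists is scored by
`net = wCCS↓ − wCCS↑`. It is retained only on the dominant side, and only
if `|net|` reaches that side's Q1 boundary magnitude — i.e. the
*imbalance alone* would rank in Q1. Otherwise the gene is predicted
unchanged (`none`), the behaviour expected for proteins targeted equally
by both cohorts. This operationalizes "sufficiently strong" as a
rank-derived threshold rather than a tuned constant; the fraction of
overlapping genes retained (~10–20% on realistic instances) is an
emergent property, not a rule.

Exact invariants, enforced by tests: conservation
(`Σ_g wCCS↑+wCCS↓ = Σ_s c_s·w_{m(s)}` to 1e-9); weight-identity
(all `w=1` reduces wCCS to the directional CCS partition); label-swap
symmetry (flipping every miRNA's direction swaps the two output lists
exactly); monotonicity (raising one up-miRNA's fold can only push its
targets' wCCS↑ more negative, never touching non-targets).

**Open choices.** The weighting functional form is `c × linear fold
magnitude` by default; `1 + log2(fold)` is available (`weight="log2"`,
identical at fold 1, gentler growth). Quartiles are computed per
direction (a union-distribution reading is also defensible; per-direction
keeps the two protein-direction hypotheses separate). Boundary ties all
take the better quartile, so Q1 can slightly exceed 25%; with all scores
tied, every gene is Q1. These are documented contracts, shared by the
brute-force oracle.

## Differential testing (SAM-style)

Two-class: `d_i = (x̄_case − x̄_ctrl) / (s_i + s0)`, with `s_i` the pooled
standard error and `s0` the 5th percentile of the `s_i` distribution (a
fixed exchangeability damper; percentile configurable). The null comes
from permuting group labels: exhaustive enumeration whenever the number
of distinct assignments is ≤ `n_perm` (e.g. the 4+4 pooled miRNA design
has only C(8,4)=70, all used), otherwise `n_perm` seeded draws.
The FDR estimate at threshold *t* is (mean permuted exceedances of *t*) /
(observed calls at *t*), with the null proportion π₀ fixed at 1 —
deliberately conservative, so that under a global null the realized call
rate at nominal q stays at or below nominal. q-values are the running
minimum down the ranking (monotone by construction), reported in percent.
Permutations are generated in a canonical sample order using subsets of
the smaller group's size, which makes the null invariant to exchanging
the case/control roles: swapping labels flips every `d` and preserves
every q exactly.

Quantitative mode regresses each feature on a continuous covariate
(fasting glucose, insulin, ...): `d_i = b_i / (se_i + s0)` with the
covariate permuted for the null; a Pearson-based statistic is available
(`method="pearson"`). A case/control fold change is undefined here, so
`fold_change` is fixed at 1.0 and the direction carries the sign.

miRNA differential calling is the two-class engine plus a strict linear
fold gate (> 1.3, i.e. >30% modulation) — a call requires *both* q ≤ 10%
and the fold. Pools are the statistical unit. Fold changes are computed
on linear group means; ratios < 1 are reported as reciprocals with
direction "down". Whether the gate should act on linear or log-scale
means is not uniquely determined; linear is used.

## Trajectory classes

Differential miRNAs are classified by their NGT → IGT → T2D group means
with a per-miRNA tolerance `tol` (default 0.5 × pooled within-group SD),
in the called direction (sign-flipped for down calls):

* **transient_igt** — IGT beyond `tol`, T2D back within `tol` of NGT;
* **late_t2d** — IGT within `tol`, T2D beyond `tol`;
* **progressive** — IGT beyond `tol`, T2D beyond `tol`, no reversal at
  the IGT→T2D step (> −tol).

A differential miRNA matching none of these is reported *unclassified*
with a warning, never silently defaulted. With 4 pools per group the
sampling noise of a group mean is commensurate with the default
tolerance, so a few percent of genuinely shifted miRNAs land
unclassified; that is a property of the tolerance heuristic, visible in
the run logs.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail with
equality, `P[X ≥ k]`, per term, BH-adjusted across tested terms. The
background is always explicit; the tissue transcriptome (not the genome)
is the correct universe, because a genome-wide reference manufactures
enrichment for anything the tissue happens to express. Terms are
intersected with the background; terms smaller than `min_term_size`
(default 3) or covering more than half the background are skipped as
uninformative. The quartile contrast runs the Q1 and Q4 lists under both
the tissue background and the predicted-target-list background.

## Delta-Ct statistics

Technical replicates are averaged per (sample, assay); ΔCt is taken
against the small-RNA reference (RNU48 by default; higher ΔCt = lower
expression); fold change vs the control group is `2^−ΔΔCt`. Group
differences use one-way ANOVA with Welch t post hocs (Holm-adjusted by
default; `holm=False` reproduces unadjusted pairwise testing); the
association with a clinical covariate is an ordinary least-squares
regression reported as R² and p.

## Synthetic data

The generators produce every pipeline input with planted, serializable
truth, at full study scale by default:

* **mRNA**: 20,000 features × (47 NGT, 26 IGT, 45 T2D); gene baselines
  log2-Normal(7, 2.5) clipped to an array-like 2–50,000 linear range,
  per-sample log2 noise SD 0.25; 10% of features generated at background
  level and flagged absent on every chip (the absent-filter truth);
  detection calls otherwise thresholded on intensity with a guaranteed
  non-absent call per surviving feature. The default effect spec is
  null — the invariant-transcriptome case. Clinical covariates are drawn
  per group around realistic cohort values (e.g. fasting glucose
  5.0/5.9/9.8 mmol/L for NGT/IGT/T2D).
* **miRNA**: 245 probes × 4 pools per clinical group; baselines a single
  continuous log2-Normal with SD 2.0 whose mean is placed so that an
  expected 30% of probes fall below the 400-unit expressed cutoff (one
  distribution split by the cutoff, as on a real chip — a discontinuous
  baseline interacts pathologically with rank-based quantile
  normalization); ~17%/~19% of expressed miRNAs shifted up/down in T2D
  (≈29 + 33 ≈ 62 of ~171) by folds in [1.5, 3.0], planted on robustly
  expressed probes (≥ 2.5× cutoff) so the truth survives the filter;
  70/30 progressive/late trajectories, plus a small transient-IGT
  fraction among unmodulated miRNAs (a truly transient miRNA has no
  NGT-vs-T2D shift and so cannot be a differential call; keeping the
  class on separate probes keeps every class individually testable);
  pool noise SD 0.15 (log2).
* **Target sites**: Poisson background (default 0.005 sites per
  miRNA–gene pair, putting ~25% of expressed genes under at least one
  site of a ~62-miRNA cohort); context scores −(0.02 + Gamma(2, 0.05)) —
  bulk near −0.1, tail to ~−0.6, all negative and right-skewed. Coherent
  sets plant 3 extra strong sites (−0.45..−0.25) per member gene from
  distinct miRNAs of one direction, so the term should surface in the
  corresponding Q1 list.
* **Ct tables**: triplicates consistent with planted 2^−ΔΔCt folds;
  replicate SD 0 gives exact recovery.

What the generators do **not** emulate: probe-level array artifacts,
batch and labeling effects, correlated co-targeting of hub genes (real
Q1 lists overlap far more than independent Poisson targeting produces —
the resolution logic is therefore additionally exercised on constructed
overlap instances), miRNA family seed-sharing, and absolute-abundance
differences between probes. Passing recovery tests therefore shows the
machinery is correct and calibrated under realistic noise, not that the
biological conclusions transfer to any particular real dataset.

## Problem sizes and determinism

All randomness flows through explicit integer seeds into NumPy's PCG64
(`default_rng`); no global RNG state is touched. Null-calibration checks
use 20 generations of 1,000-feature/10+10-sample matrices at 200
permutations; recovery checks use 20 replicates of the study-scale miRNA
arm with a 2,500-gene target universe; oracle-equivalence sweeps use 100
random instances of ≤ 50 genes × ≤ 10 miRNAs. The full study-scale run
(20,000 × 118 mRNA matrix, 1,000 permutations) completes in well under a
minute on one CPU; permutation blocks are chunked to bound peak memory.

## Known limitations

* π₀ = 1 makes the permutation FDR conservative; on strongly
  non-null data q-values are somewhat inflated (never anti-conservative).
* Quantile normalization attenuates true fold changes when a third of
  features shift (the common reference distribution absorbs part of the
  shift), so planted folds near the 1.3 gate are occasionally lost —
  visible in recovery runs and inherent to the normalization, not a bug.
* The site-level synergy of closely spaced heterogeneous sites and
  absolute miRNA abundance are deliberately not modelled; both are known
  refinements that would require inputs the pipeline does not assume.
* Flat gene-set membership only: ontology-graph ancestor propagation, if
  wanted, must be pre-applied to the collection.
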