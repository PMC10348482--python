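# Methods

## Model

`abguilds` treats a binary genome × function matrix `Y` (G genomes, F
functions; rows genomes, columns functions) as independent Bernoulli
observations of an underlying probability matrix `V = Γβ`. Each genome's
row of `Γ` is a probability vector over `K` latent *aspects*; each row of
`β` gives, per aspect, the probability that a function is present. A
latent indicator `Z_gfk` records which aspect generated cell `(g, f)`.
The complete-data model is

```
Z_gf· ~ Categorical(Γ_g·),   Y_gf | Z_gfk = 1 ~ Bernoulli(β_kf)
```

so the marginal `P(Y_gf = 1) = Σ_k Γ_gk β_kf = V_gf`. Because presence
probabilities are never exactly 0 or 1, occasional false absences (e.g.
incomplete genomes) or false presences are absorbed as low-probability
Bernoulli outcomes rather than breaking hard cluster assignments.

Assumptions worth stating: cells are conditionally independent given
`(Γ, β)`; genomes are exchangeable; the latent dimension `K` is fixed by
the user. Aspect labels are non-identifiable (any permutation gives the
same likelihood), so aspects are reported sorted by decreasing total
genome weight `Σ_g Γ_gk` for stable output; scientific conclusions should
rest on guild content, not aspect indices.

## EM fitting

The E-step posterior is `resp_gfk ∝ Γ_gk β_kf` when `Y_gf = 1` and
`∝ Γ_gk (1 − β_kf)` when `Y_gf = 0`, normalised by `V_gf` or `1 − V_gf`.
The M-step re-estimates `Γ_gk` as the mean responsibility over functions
and `β_kf` as the responsibility-weighted fraction of presences. Both
steps are folded into four G×F×K matrix products, so the G×F×K
responsibility tensor is never materialised and a 3,840 × 212 fit at
K = 10 takes seconds per restart.

Numerical choices:

- `V` is clipped to `[1e-12, 1 − 1e-12]` before divisions and logs;
  perfect fits otherwise drive `V` to 0/1 and the E-step divides by `V`.
- Initialisation: `Γ` rows from a flat Dirichlet, `β` entries from
  Uniform(0.25, 0.75) — boundary starts would freeze responsibilities.
- Stopping: a fixed iteration cap (default 500, where the likelihood has
  plateaued on matrices of this scale) or a relative log-likelihood change
  below 1e-10, whichever comes first.
- Restarts: 10 by default; the restart with the highest final
  log-likelihood wins. Every restart's seed derives deterministically from
  `(seed, restart index)`, making fits bit-reproducible.
- A restart whose likelihood becomes non-finite is aborted and counted; a
  fit fails only if all restarts abort.

The log-likelihood trace is non-decreasing (a property test enforces
−1e-9 per step as the tolerance for float accumulation).

## Scoring and guilds

`r_fk` averages the presence-attribution posterior
`Γ_gk β_kf / V_gf` over **all** G genomes, not only those carrying `f` —
the literal form of the marginal score. The alternative conditional mean
(averaging only over carriers) is exposed as `conditional=True` /
`--conditional-r` because it is sharper when aspects partition genomes
cleanly, but it is not the default. Representative sets `A_k` take each
genome's argmax aspect subject to `Γ_gk > 2/K` (strict); ties go to the
lowest aspect index with a warning. Note `K ≤ 2` makes the threshold
≥ 1, so every genome is excluded and `q` (hence `s`) is identically zero:
guild extraction needs `K ≥ 3` to be meaningful, and an aspect with empty
`A_k` is reported as unrepresented (zero `q` column, warning) rather than
an error, as is an `A_k` whose genomes carry no functions.

Rankings sort by descending `s` with ties broken by ascending function ID
(deterministic). Guild definitions: fixed top-`m` (default 5, minimum 2),
or the **largest** prefix (starting at size 2) whose mapback count still
meets the support threshold (default 100, compared with ≥). Largest is
chosen because mapback counts are non-increasing in prefix size, so the
largest satisfying prefix is the most informative guild the data support;
if even size 2 fails the guild is returned flagged `below_threshold`.
Guilds from different aspects may share functions — overlap is a feature,
not an error.

Confidence `Conf(A→B)` with zero antecedent support is *missing*, not 0
or 1 (the ratio is undefined and coercion would bias the minimum-
confidence summary); summaries skip missing pairs and report how many
were skipped. The diagonal is excluded from summaries (always 1).

## Synthetic data and what it does (not) show

`generate_base_matrix` draws a ground-truth decomposition — Dirichlet
genome weights over `n_latent` aspects, `β` rows a mix of high (0.9) and
low (0.05) entries rescaled to a target overall density (attainable range
0.05–0.9) — and samples `Y` from it. This emulates the *structure* the
model assumes: blocks of co-occurring functions embedded in background
noise at realistic density (default 0.3, a typical fill for curated
pathway tables). It does **not** emulate phylogenetic correlation between
genomes, annotation-pipeline biases, nested genome completeness, or
core-function columns shared by nearly all genomes; `flip_noise` adds
only i.i.d. annotation error. Passing recovery tests therefore shows the
method does what it claims *when its structural assumptions hold* — on
real data the appropriate `K` and the separability of guilds must be
re-established with the same planted-guild sweep.

Planted guilds are perfect by construction: round(abundance × G) member
genomes (round-half-up, so 2% of 3,840 gives 77) carry all of the guild's
appended columns, all other genomes none. Non-overlapping insertion draws
members without replacement from unclaimed genomes; the random variant
draws each guild's members independently (overlaps allowed) while keeping
exact member counts. Defaults mirror the simulation design: sizes 5/7/9,
abundances 2/5/10 %, 100 replicates (20 at desk scale).

## K selection

A guild counts as *hit* in a fit when all its functions sit within the
top 15 (`top_window`) of at least one aspect's ranking; *extra hits* are
surplus such aspects per guild, summed. The sweep reuses the same
replicate datasets across `K` so differences along the sweep reflect `K`
alone, and recommends the `K` values maximising mean hit rate among those
with mean extra hits ≤ 0.05 (an allowance for rare duplications at
desk-scale replicate counts). An empty recommendation with a diagnostic
means every swept `K` over-fits — sweep smaller `K`.

Observed regimes on the surrogate (1,000 × 200 base, 5 latent aspects,
three planted guilds, fits with 500 iterations): at the matched
`K = 8` strong guilds (9 functions, 10%) are recovered essentially always
with no extra hits; at `K = 4` rare guilds (5 functions, 2%) are missed
but never duplicated; at `K = 16` extra hits appear. These are the three
regimes the selection heuristic distinguishes. The under/over-fit checks
use 10 replicates and the matched-K check 20, with 2 restarts per fit —
sizes chosen so the full suite stays desk-scale while binomial error on
the means stays far from the asserted thresholds.

## Known limitations

- `K` must be supplied; the sweep is a heuristic, not an estimator, and
  information-criterion selection is out of scope.
- The literal all-genome `r` can saturate toward `1/K` for functions
  wholly owned by one aspect when `V → 0` cells dominate the average
  (visible in degenerate two-block examples at `K = 2`); the `q`
  adjustment is what restores discrimination in practice.
- Aspect count, not guild count: aspects whose representatives are empty
  still produce (degenerate) rankings; downstream code should check the
  unrepresented warning.
- Mapback enumeration is exact conjunction; a single false absence
  removes a genome from a guild's mapback set. This is faithful to the
  definition but sensitive to annotation completeness.
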