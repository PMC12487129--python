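# Methods

This note records the models, conventions and numerical choices behind
`bloomics`, in the spirit of a statistical package's model documentation.

## Growth from two timepoints

Each experiment incubates seawater for T hours (36 h in winter and summer,
48 h in spring and fall; overridable per season). For a genome with
replicate-mean relative abundances a₀ at t0 and a_f at tf,

    FC = a_f / a₀,   μ = ln(FC) / T,   FEDT = ln 2 / μ.

Replicates are averaged arithmetically before the ratio; presence is called
per timepoint on replicate-mean breadth of coverage with an inclusive 25 %
threshold. The imputation conventions:

* present → absent: FC = 0.1, FEDT = 500 h (flag `disappeared`);
* absent → present: FC = 100 (flag `appeared`; the resulting FEDT,
  T·ln2/ln100 ≈ 5.4–7.2 h, is eligible for the fast class and carries its
  flag);
* absent at both: no fold-change, excluded from comparisons;
* FC ∈ (0, 1] with both presences: the doubling time would be negative or
  infinite, so it is also set to the 500 h ceiling and flagged
  (`fedt_ceiling`) distinctly from disappearance.

Growth classes come from the minimum FEDT over seasons within a treatment:
fast < 12 h, slow > 120 h, medium otherwise; both boundaries assign to
medium ("less than" and "higher than" are strict). Genomes with no defined
FEDT in a treatment are `unclassified`. These two-timepoint estimates cannot
see growth-then-decline within an incubation; that limitation is inherent to
the design, not to the implementation.

## Codon usage bias

Per gene, MILC is computed over synonymous codon families of size r_a ≥ 2
(stop codons and the single-codon families Met and Trp excluded):

    MILC = (Σ_a Σ_{c∈a} o_c · ln(f_c / g_c)) / L − C,
    C = (Σ_{a present} (r_a − 1)) / L,

with o_c the gene's codon counts, f_c its within-family frequencies, g_c the
within-family reference frequencies from the pooled full gene set, and L the
number of counted codons. The distance term is a within-family
log-likelihood-ratio statistic and is non-negative for proper f and g; C
removes its finite-length inflation (families present in the gene only).
Reference frequencies receive a pseudocount of 1 per codon before
normalisation, so no observed codon meets a zero reference. Genes are read in
frame from position 0, trailing partial codons trimmed, ambiguous-base codons
ignored; genes with internal stop codons are skipped with a warning. A
genome's CUB is the arithmetic mean (not median) MILC of its highly expressed
genes, supplied as an explicit ID list. Doubling all of a gene's codon counts
leaves f and distance/L unchanged while halving C, so MILC is not strictly
duplication-invariant; the documented behaviour is asserted in tests.

Trophic strategy uses the estimated minimum doubling time (EMDT) as an input
column — the regression mapping CUB to EMDT is a fitted model of an external
predictor whose coefficients are not public, so it is deliberately not
re-fitted here. Copiotroph ⇔ EMDT < 5 h. EMDT–FEDT agreement is summarised by
the Pearson correlation of (EMDT, minimum FEDT over all experiments).

## Enrichment testing

FU percentage tables are 100 · count / gene_count with the CheckM-predicted
gene count as denominator; a gene contributes one count to every FU it maps
to, and a multi-letter COG category string like `KT` counts once for K and
once for T (CAZY categories are the alphabetic prefix of the family
accession). FUs whose percentages summed over all genomes fall below 5 are
filtered out (boundary inclusive).

Wilcoxon rank-sum p-values are exact whenever the smaller group has ≤ 8
members: the null distribution of the midrank sum over all C(n₁+n₂, n₁) label
assignments is built by dynamic programming, and the two-sided p is the
probability of a rank sum at least as far from its null mean as observed.
Midranks make the enumeration correct under ties, which the tie-corrected
normal approximation (used for larger groups, with continuity correction)
only approximates. Benjamini–Hochberg adjustment is the usual step-up with
families defined per annotation system × treatment × comparison — the most
conservative family consistent with per-treatment reporting. Significance
defaults to adjusted p < 0.05 with a switch for raw p; enrichment direction
is the sign of the group-mean difference, so "enriched in fast-growers" is a
post-hoc reading of a two-sided test. In pairwise (≥ 3 group) mode all FU ×
pair tests of one system form a single BH family. Medium-growers are excluded
from fast-vs-slow comparisons; groups below two members are skipped with a
warning.

Per-treatment significant sets are intersected upset-style: each FU belongs
to exactly one combination (the exact set of treatments where it is
significant), and combinations with fewer than 3 members are dropped from the
report. The biogeochemical screen reuses the pairwise machinery per marker
gene (percentages of its KOs summed) and labels genes fast-/slow-enriched by
the fast-vs-slow pair; the shipped gene → KO map covers the twelve named
markers and is caller-extensible. Heatmap matrices are ordered by
hierarchical clustering with Euclidean distance and complete linkage, fixed
for determinism; rendering is out of scope.

## Bloomers

A population bloomed in an experiment iff FEDT < 12 h, a₀ < 1 % and
a_f > 1 % (strict inequalities: exactly 1 % fails). A genome is a bloomer if
it bloomed at least once. Bloomer-vs-copiotroph trait tests (genome size,
G+C, EMDT, CUB) are rank-sum tests BH-corrected across the four traits.

## ASV growth

Pseudoabundance = relative abundance × flow-cytometry total cells. For each
series, zero points are removed and every contiguous window of ≥ 3 surviving
points is fitted by OLS of ln(pseudoabundance) on time; among windows whose
slope t-test gives p < 0.05 the maximum slope wins, ties broken by smaller p
then earlier start. Windows are contiguous to preserve the exponential-phase
interpretation. The selected slope is reported even when negative (doubling
time NaN), flagging declining populations rather than hiding them. Isolate
matching trims isolates to configured V4–V5 coordinates and requires exact
string identity (optionally after reverse complement); selection additionally
requires the matched ASV to cross the 1 % line with a fitted doubling time
≤ 24 h (inclusive).

## Synthetic data

The generator plants a two-class community: copiotrophs are fast responders
(base FEDT uniform on 7–11 h, divided by treatment multipliers
CL = CD = 1.0 < PL = PD = 1.1 < DL = 1.3 < VL = 1.5) and oligotrophs are slow
(base FEDT 200–500 h, unresponsive); the ranges are placed so classes never
cross the 12/120 h boundaries, and EMDTs are drawn consistently (1–4.5 h vs
5.5–30 h). Because a planted FEDT of ~8 h over 36–48 h implies relative-
abundance fold-changes of 10–4000×, final abundances are planted first —
bloomers at 2–4 %, other fast growers at 0.1–0.45 % (clear of the 1 % bloom
line so that noise cannot promote them), oligotrophs from initial 1–3 % times
their small fold — and initial abundances derived as tf/exp(μT). The emitted
table therefore satisfies tf = t0 · exp(μT) · ε exactly, with multiplicative
lognormal noise ε (σ = 0.2 by default) on final abundances only, keeps
per-sample sums on the 0–100 % scale, and is not renormalised (mapped-read
fractions need not sum to 100). Breadth is 0.95 for present entries.

FU counts are Poisson with rate (target percentage × gene_count / 100);
baseline percentages are uniform on 0.05–0.5 % per FU and the planted
enrichment adds 1 percentage point for fast genomes in the chosen FUs
(defaults: 300 FUs, 10 enriched, 40 genomes, half copiotrophic, 3 bloomers —
chosen to mirror a desk-scale version of a genome-resolved bloom experiment).
CDS are drawn codon-by-codon: background genes uniformly within synonymous
families, highly expressed genes of copiotrophs from a distribution in which
a fraction θ (default 0.9) of each family's mass moves to one preferred
codon. θ = 0 reproduces the background exactly (null case). The amplicon
generator plants exactly log-linear pseudoabundances for growing ASVs,
derives relative abundances by closure over the community (so cytometry
totals and relative abundances are mutually consistent), and emits one
isolate copying a blooming ASV's V4–V5 region exactly, one with a single
substitution and one unrelated.

What the generator does **not** emulate: compositional coupling between
genomes (abundances are planted independently subject to the sum budget),
saturating growth curves, medium-growers as a planted class, replicate-level
presence/absence discordance, chimerism or contamination artefacts, and any
mechanistic ecology (predation, lysis). Passing recovery tests therefore
shows the estimators invert the stated generative model, not that they are
robust to every failure mode of real metagenomic data. With default noise,
two-timepoint FEDTs of slow growers scatter across the 120 h boundary — a
realistic property of the estimator, visible in the README example.

## Problem sizes and determinism

All randomness flows from a single integer seed through one generator
instance; equal seeds give byte-identical outputs. Simulation-based test
suites use 50 replicates at the sizes stated in their docstrings (40 genomes
× 300 FUs for FDR and power; 16 genomes × 60 genes × 150 codons for the
codon-bias separation checks, a size at which the CUB group difference is
already far larger than its Monte-Carlo error). The exact Wilcoxon/BH/window
oracles run exhaustively at n ≤ 10, on 1000 random p-vectors, and on 500
random series respectively.

## Known limitations

* The exact rank-sum branch switches to the normal approximation above group
  size 8; near the switch the two can differ in the third decimal.
* `fit_max_growth` fits every window independently; overlapping-window
  multiplicity inflates the family-wise rate of finding *some* significant
  window under the null (single-window series stay at the nominal level).
* The EMDT input is trusted as given; no attempt is made to re-derive it
  from CUB.
* Sample labels must parse under the configured grammar; unparseable rows
  are skipped (with warnings), not guessed.
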