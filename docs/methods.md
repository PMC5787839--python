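# Methods

## Methylation levels and nonconversion correction

Every cytosine on either strand whose two downstream bases are determined
(inside the chromosome, no N) is a site; its context is CG, CHG or CHH
(H = A/T/C) from those two bases read 5'→3' on the site's strand. The raw
level of a site with `m` methylated and `u` unmethylated read calls is
`ML = m/(m+u)`. Bisulfite nonconversion makes an unmethylated cytosine read
as methylated with probability *r*, so the observed level has expectation
`ML·(1−r) + r`; the corrected level `(ML − r)/(1 − r)` inverts this exactly
and is clamped to [0, 1] (negative values arise at unmethylated sites by
sampling noise and are probabilities, hence the clamp). *r* is the pooled
methylated-read fraction over the unmethylated lambda spike-in chromosome;
estimation requires at least 10⁴ pooled spike-in reads (configurable),
otherwise an explicit `--nonconversion-rate` must be supplied.

A site is **covered** when it has ≥ 4 reads (default `min_coverage`; chosen
so that ~10× mean coverage keeps most sites while suppressing
single-read noise). All pooled summaries use covered sites only.

**Per-site mC calls.** Genome-wide "percent methylated sites" summaries need
a binary call. We test each covered site's methylated count one-sided
against Binomial(coverage, r) and apply Benjamini–Hochberg FDR across all
covered sites; a site is mC iff q < 0.05. This is the standard
error-rate-calibrated call for WGBS data; it is a documented choice, not a
universally fixed convention, and the FDR level is configurable.

**Windows.** Window summaries pool counts (never average per-site levels) in
3000-bp windows stepped by 600 bp; the window level is Σm/Σ(m+u) over
covered sites of the context, flagged undefined when the denominator is 0.
Window starts advance by the step while full windows fit; when the next
window would overrun the chromosome end, one truncated terminal window is
emitted iff at least half a window remains (shorter slivers are
high-variance and dropped). Window levels are nonconversion-corrected by
default (flag to disable). Symmetric-CpG strand merging is available as an
explicit operation, never applied implicitly; strands are otherwise reported
separately.

## DMR calling

Between two conditions (replicates pooled per condition by count summation,
giving a single 2×2 table per window — the two-sample sliding-window
design), every 1000-bp window stepped by 100 bp with ≥ 5 covered cytosines
of the context in *both* conditions is tested: the two-sided Fisher exact
p sums hypergeometric probabilities of tables no more likely than the
observed one (relative tie slack 1+1e-7), computed vectorised via log-gamma
binomial coefficients and verified against exact rational enumeration.
q-values are BH-adjusted per context across all tested windows genome-wide
(contexts differ greatly in site density and effect scale, so pooling them
in one FDR pass would let the dense context dominate). Significant windows
(q < 0.05 and |ΔML| ≥ 0.1 — the level filter suppresses statistically
significant but biologically trivial differences at high counts) merge when
overlapping or book-ended with the same context and direction; merged-span
levels are recomputed from pooled counts. Status is *hyper* when the
case/treatment level exceeds control.

Genes are assigned a DMR by ≥ 1 bp overlap of the promoter (2 kb upstream of
the transcript start, strand-aware), gene body (transcript span) or TTR
(2 kb downstream of the transcript end, symmetric with the promoter since no
established TTR span exists); a gene can be both hyper- and hypomethylated
through different regions or contexts and is then counted in both
categories. Per-TE tests pool counts over the TE span per context (plus a
combined all-context test), BH-adjust across TEs within a context, and call
a TE differential iff q < 0.05 **and** the level fold change exceeds 2,
where fold = (ML_case + 0.01)/(ML_control + 0.01) or its inverse — the 0.01
pseudocount keeps the fold finite at unmethylated TEs. A flag switches the
significance criterion to raw p < 0.05 for analyses that apply the FDR
adjustment separately.

## Profiles and quintiles

Compartment precedence for overlapping bases is TE > gene subfeature
(5'UTR/exon/intron/3'UTR) > promoter/downstream flank > intergenic; the
spike-in chromosome is its own compartment. Note the painted "exon"
compartment excludes UTR bases, so it corresponds to CDS-like exonic
sequence. Metagene profiles rescale each gene to a fixed axis — 20 promoter,
5 5'UTR, 20 body, 5 3'UTR and 20 downstream bins over 2-kb flanks — with
counts pooled per bin across genes and minus-strand genes mirrored; each
cytosine in the feature-plus-flanks span lands in exactly one bin, so binned
counts conserve totals exactly. TE profiles use 20/20/20 bins
(upstream/body/downstream). Fixed bin counts (rather than per-bp profiles)
give a deterministic axis for pooling variable-length features; genes
shorter than the bin count simply leave some bins empty.

Quintile partitions rank items ascending and split them into five groups
whose sizes differ by at most one (larger groups at the low end; ties broken
by stable input order). Special classes are extracted first: genes with
FPKM < 0.1 are *nonexpressed*; a gene region is *unmethylated* when it has
fewer than 5 covered cytosines or no FDR-called mC site (a documented
stand-in — there is no field-standard "methylated gene" criterion). Genes
whose region has no covered cytosine at all are excluded and tallied.
Expression is summarised as log10(FPKM + 0.01) with linear-interpolation
quartiles and 1.5·IQR whiskers (the most extreme data point inside the
fence).

## Expression integration

DE labels (up/down/none) are inputs; no DE caller is implemented (detecting
differential expression from RNA-seq counts is a separate, well-served
problem). Overlaps of hyper-/hypomethylated gene sets with up-/down-regulated
sets are reported with exclusive Venn counts and a hypergeometric enrichment
p against the expression-table universe. Group comparisons of per-gene
log2((FPKM_case+0.01)/(FPKM_control+0.01)) use the two-sided Wilcoxon
rank-sum test: exact (full null distribution) when the smaller group has
≤ 8 values and there are no ties, otherwise the normal approximation with
tie and continuity corrections. The 2^−ΔΔCt helper implements comparative-Ct
relative expression against a reference gene and calibrator condition.

## Synthetic data generator

The generator emulates a plant WGBS stress experiment at desk scale:

* **Genome.** Random sequence at 38% GC on a configurable set of
  chromosomes; genes (Poisson exon counts, uniform exon/intron/UTR lengths,
  UTRs inside the terminal exons) and TEs (log-normal lengths, configurable
  class mix over LTR_Gypsy/LTR_Copia/hAT_Tag1/hAT_Tip100/other) are placed
  without overlap with multinomially distributed gaps; an unmethylated
  lambda-sized (48,502 bp) spike-in chromosome named `lambda` is appended.
  Requested compositions that do not fit raise a capacity error.
* **Truth methylome.** Each cytosine is methylated with a compartment- and
  context-specific probability *p* (the "context level"); methylated sites
  draw their true ML from a per-context Beta (defaults: CG Beta(8,2),
  CHG Beta(5,3), CHH Beta(2.5,4.5)), unmethylated sites are 0. This bimodal
  mixture is what makes "percent methylated sites" a recoverable, configured
  quantity — a unimodal per-site Beta cannot control it. Defaults give
  apple-like genome-wide levels (~54/38/8.5% CG/CHG/CHH) with TEs
  hypermethylated, a 5'UTR dip and CHH highest in promoters. A point-mass
  option (`fixed`) supports degenerate configurations; an optional slope
  makes TE CHH levels decline with TE length.
* **Planted DMRs.** Non-overlapping intervals (default 1–2 kb, 2-kb margin)
  shift the chosen context's true ML by ±0.4 (clamped); the direction is
  chosen adaptively (hyper where the local baseline is below 0.5) so the
  clamped shift always moves the pooled level in the planted direction.
  Case truth equals control truth outside planted intervals.
* **Counts.** Coverage is Poisson(10) per site (matching ~10× mean depth
  with realistic dispersion and exercising the coverage filter); methylated
  counts are Binomial(coverage, ML·(1−o) + (1−ML)·r) with nonconversion
  r = 0.0012 (conversion 99.88%) and over-conversion o = 0 by default — the
  one-parameter noise model that the correction inverts. Two biological
  replicates per condition by default; each sample-replicate has a
  deterministic RNG stream derived from (seed, condition, replicate), so
  fixed seeds give byte-identical outputs.
* **Expression.** Expressed genes draw log-normal FPKM (re-drawn above the
  0.1 nonexpression threshold), a configured fraction is forced below
  FPKM 0.1, and a configured DE fraction receives 2–6× fold changes split
  between up and down. Optionally, genes whose promoter overlaps a planted
  hypermethylated interval are biased toward "down", emulating
  promoter-methylation-driven repression.

**What the generator does not emulate:** read-level artifacts (M-bias, PCR
duplicates, mapping bias), sequence evolution of TE families, linkage
between neighbouring sites beyond compartments, and biological replicate
dispersion beyond binomial sampling. Passing tests therefore demonstrate
correctness of the estimators and callers under the stated noise model, not
robustness to alignment-level artifacts.

## Problem sizes and numerical choices

The test and acceptance workloads use 0.4–1 Mb genomes at 10× coverage with
50 planted CG DMRs of ΔML 0.4 — large enough that window tests pool
hundreds of reads and recall/calibration are stable, and a size the package
processes in seconds to a couple of minutes. Fisher p-values agree with
exact rational enumeration to < 1e-12 for N ≤ 60; BH q-values match the
independent step-up formula; the exact Wilcoxon path matches full
enumeration for all tie-free splits with n ≤ 10. Degenerate inputs are
explicit: all-zero Fisher tables give p = 1 with a warning; windows or
profile bins without covered sites are flagged undefined rather than 0;
empty compartments are reported missing; unpaired CpG sites pass through
merging flagged.

## Known limitations

* Replicate pooling discards between-replicate dispersion; a beta-binomial
  window model would be more conservative with many replicates.
* The mC-site caller and the "methylated gene" criterion are calibrated,
  documented conventions; published percentage summaries built on different
  conventions will differ systematically.
* The TTR is taken as the 2-kb downstream flank; analyses sensitive to the
  exact termination-region definition should adjust `ttr_span`.
* DMR boundaries are window-resolution (±window size); merged spans can
  extend past the true differential interval, diluting the reported ΔML.
* Whether window levels should use raw or corrected ML is not standardised;
  the default is corrected with a flag to disable.
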