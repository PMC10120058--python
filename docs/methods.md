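# Model and methods

## The question and the model

Herbicides impose some of the strongest selection pressures measured in
plants. Target-site resistance (TSR) arises through a handful of specific
codon substitutions in the gene encoding the herbicide's target enzyme
(here modelled on ACCase, with ALS1 supported in the typing module). The
package asks whether TSR alleles that sweep through a field population
after spraying begins were already segregating beforehand (standing
genetic variation, SGV) or arose afterwards (de novo), and provides three
coordinated tools: a forward simulator of the locus, closed-form sweep
probabilities, and typing utilities for phased amplicon haplotypes.

### Forward Wright–Fisher simulator

A diploid population of constant size N evolves at a single linear locus.

* **Locus template.** 12,250 sites split into exons and noncoding
  sequence. The real gene's exon count and coding fraction are not part of
  the shipped defaults with any authority: `n_exons = 10` and
  `coding_fraction = 0.5` are placeholders for a generic gene model, and
  users modelling a specific gene should supply `exon_intervals` from an
  annotation. Seven exonic nucleotides form the TSR mutational target
  (evenly spread by default, placeable explicitly). Coordinates are
  0-based half-open; site classes are exhaustive and mutually exclusive
  with precedence `tsr_target > exonic > noncoding`.
* **Mutation.** Per-gamete Poisson(μL) events at uniform sites, with
  μ = 3.0 × 10⁻⁸ per site per generation (a maize-derived rate). Finite
  sites with recurrence: every event gets a fresh `origin_id`, so
  independent origins at the same nucleotide remain countable; a new event
  replaces an existing derived allele at the same site on the same gamete.
* **Fitness effects.** Noncoding and intron mutations are neutral. Exonic
  mutations are neutral with probability 0.25, otherwise deleterious with
  s drawn from −Gamma(shape 0.245, mean 1.54 × 10⁻⁴) — the stated mean is
  the mean of the deleterious class itself, not diluted over the neutral
  fraction — and dominance h = 0.5 (conventional default; the source
  material is silent on background dominance). Genotype fitness is
  multiplicative across sites: 1, 1 + hs, 1 + s. TSR mutations carry
  `tsr_s_before` (default 0) until herbicide onset.
* **Recombination.** Per-gamete Poisson(r (L−1)) crossovers at uniform
  breakpoints, r = 7.4 × 10⁻⁹ (genome-wide maize average).
* **Burn-in.** 10 N generations from a mutation-free start; this exceeds
  the coalescent time scale and delivers mutation–selection–drift balance
  (verified: E[θ̂_W] = E[π̂] = 4Nμ within Monte-Carlo error).
* **Herbicide phase.** 30 generations; one application per generation.
  Individuals carrying ≥ 1 TSR allele (dominant) receive a parental
  sampling weight `survival_ratio` (default 20) times their background
  fitness — soft selection at constant N, chosen because the populations
  being modelled persist through treatment. An alternative "coefficient"
  mode gives TSR genotypes fitness 1 / 1+hs / 1+s instead, which is what
  the analytic theory assumes and what the theory-vs-simulation oracle
  tests use.
* **Rescaling.** `rescale_config` applies the standard λ-rescaling: N/λ,
  μλ, rλ, and all selection coefficients ×λ at draw time, preserving 4Nμ,
  4Nr and Ns. The survival ratio is *not* rescaled: it is a bounded
  viability ratio, not a small coefficient. A rescaling-invariance test
  (λ = 10 vs λ = 20 on an N = 8,000 base protocol, a problem size chosen
  so the paired sets complete quickly) guards this choice.

Replicates are classified at the end of the herbicide phase: among TSR
origins present at frequency ≥ 1/(2N) (one copy — the most literal reading
of "present"; the threshold is configurable), a replicate is `sgv` if any
surviving origin predates onset (mixed runs count as `sgv`), `de_novo_only`
if all survivors arose during selection, and `none` otherwise.

### Engine design

The default `linked` engine is an exact haplotype-level implementation
(numba kernel): haplotypes are sparse site-sorted mutation lists with
copy-on-write gametes, cached per-haplotype fitness factors with an exact
lazy homozygosity correction inside a rejection sampler, Poisson-total
event placement (equivalent to per-gamete draws by superposition), and an
exact fast-forward across generations in which no mutation segregates
(the population is then exchangeable). A linkage-free `freq` engine
(per-mutation binomial updates with marginal HWE selection) cross-checks
linkage-insensitive summaries. All randomness in a replicate flows from
one seeded generator; runs are bit-reproducible given their seeds.

### Analytic sweep probabilities

For a beneficial target of L nucleotides with per-site rate u, write
Θ = 4Nₑ u L and α = 4 Nₑ h s. The standing frequency density of an allele
that was neutral-to-deleterious before onset (heterozygous effect
h_del s_del) is ∝ Θ x⁻¹ e^{−α_d x}; a standing class at frequency x
escapes loss under the new selection regime with probability
1 − e^{−α_b x}. Integrating gives

    P_sgv = 1 − exp[ −Θ ln(1 + α_b / (α_d + 1)) ].

New copies arise at 2Nₑ u L per generation during the T-generation window
and each establishes with the diffusion probability
π_est = (1 − e^{−2hs}) / (1 − e^{−4Nₑhs}), so

    P_dn = 1 − exp( −2 Nₑ u L T π_est ),

and the two routes combine independently:
P_total = P_sgv + P_dn − P_sgv P_dn. "Adaptation" means establishment
(escape from stochastic loss), not completed fixation, matching the short
selection horizon. These forms are validated against the package's own
forward simulator at small Nₑ (with a boosted mutation rate for
statistical power, and an extended post-window drift phase so unresolved
lineages resolve before scoring). Defaults h_ben = h_del = 0.5; the
conditional fraction P_sgv/P_total is reported alongside the
unconditional P_sgv because either may be wanted.

### Amplicon haplotype typing

Inputs are phased haplotype sequences (`>sample|population|gene|phase`
FASTA), a reference, and a codon table (codon number, reference amino
acid, resistant amino acids, reference coordinates of the codon). Each
haplotype is anchored to the reference by global pairwise alignment
(biopython `PairwiseAligner`; equal-length pairs below 20% divergence map
by identity as a fast path) and each listed codon is translated: resistant
calls are labelled (`"ACCase Ile1781Leu"`), codons containing a gap or N
are reported *uncallable*, never silently wild type. Deduplication is
exact sequence identity after uppercase/gap normalisation, mirroring
"nonredundant haplotypes"; the sharing table counts clusters found in ≥ 2
populations and feeds the Yates-corrected χ² test (the corrected form is
the default because it is the variant that reproduces the
worked example's p-value from its counts; the uncorrected form is exposed).

Independent-origin counting masks the resistance codon, groups carriers by
backbone with single-linkage at ≤ `k_backbone` (default 3) mismatches —a
guard against residual sequencing noise— and downgrades a backbone to
*putative recombinant* when its representative equals a single-breakpoint
mosaic of one observed resistant haplotype and one observed wild-type
haplotype (exhaustive prefix/suffix scan). Because a mosaic and its donor
can each "explain" the other, calls are made greedily in order of
descending carrier count (parsimony: the commonest haplotype is treated as
the origin); an exact count tie is reported `ambiguous` rather than
silently resolved. The per-field total counts distinct resistant
haplotypes not explained as mosaics under the same order.

### Synthetic panels

The generator plants a star of backbones around a deterministic 2-kb mock
reference that carries the real TSR codon contexts at scaled coordinates
(the full ~13 kb amplicon is unnecessary for exercising the logic). Each
non-reference backbone receives a fixed number of private substitutions at
sites of its own, so pairwise divergences are realised exactly (2d between
two non-reference backbones). TSR events apply minimal-edit resistant
codons to chosen backbones in chosen populations; recombinants are exact
single crossovers carrying the resistance codon side. Panels are
deterministic given their seed and ship truth tables sufficient to score
calling, deduplication, sharing and origin counting. The generator is
*not* coalescent-realistic (no shared genealogy, no recurrent sequencing
error, no indel process beyond what tests inject); passing its truth
recovery says the typing logic is correct on unambiguous data, not that
real panels are unambiguous.

## Problem sizes

The full-scale study design (1,000 replicates at N = 42,000 with 420,000
burn-in generations each) is far beyond a desk machine. The shipped
experiment sizes are: acceptance script, 200 replicates at λ = 20
(N′ = 2,100, 21,000-generation burn-ins; ≈ 15–20 min on one CPU); test
suite, 80 replicates for the protocol check, 800-replicate theory oracles
at Nₑ = 250 with μ boosted to 2 × 10⁻⁵ for power, 20,000 fixation trials
at N = 100, and 120-replicate rescaling pairs at N = 8,000. Tolerances are
3 standard errors at these sizes (plus a documented ±5-percentage-point
rescaling allowance for the protocol proportions).

## Known limitations and one open disagreement

* No spatial structure, seed bank, selfing, migration or metapopulation
  dynamics; no polygenic (non-target-site) resistance.
* The neutral-exon model variant (`p_neutral_exon = 1`) is supported; a
  numerical corner exists where gamma effects of order 10⁻¹² round the
  homozygote correction above 1 and force the slower exact-scan sampler —
  harmless, but worth knowing when profiling.
* **The 20× survival advantage under soft selection cannot reproduce the
  reported de-novo proportions.** With carriers receiving 20× parental
  weight at constant N, a single new TSR copy expects ~20 transmitted
  copies next generation and essentially never drifts out
  (loss ≈ e⁻²⁰). Since 2Nμ·7·30 ≈ 0.53 de novo events arrive per
  replicate regardless of rescaling, ~30% of replicates end with
  only-de-novo resistance and ~12% with ≥ 2 surviving origins — an order
  of magnitude above the field-study values this protocol is modelled on
  (4.2% and 41/1000), while the
  standing-variation proportion (~27% vs 25.5%) matches well because it is
  controlled by the standing input Θ·a₂ₙ₋₁ alone. The reported numbers are
  mutually consistent only with a per-copy establishment probability near
  0.1, which a pure *relative* survival ratio cannot produce at constant
  N; an all-or-nothing viability lottery (adults survive treatment with
  absolute probabilities p_r = 20 p_s *before* reproducing, inflating
  offspring-number variance) would, but requires an absolute survival
  rate that is not stated anywhere and so is not implemented. The
  simulator therefore keeps the literal soft-selection rule, and the
  solely-de-novo and multi-origin statistics are expected to overshoot
  the reference values; the standing-variation proportion and all
  analytic results are unaffected.
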