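# Methods

## Scope

`autozyg` maps a fully penetrant autosomal-recessive trait in consanguineous
families from exome-style variant calls. The pipeline assumes a single
ancestral mutation (every affected is homozygous by descent for one founder
haplotype), autosomal inheritance, and marker data dense enough to expose
multi-megabase autozygous runs. Everything upstream of variant calls
(alignment, variant calling, capture chemistry) is out of scope; calls,
read-count matrices and annotation tables are inputs.

## Zygosity calling and AOH segmentation

A site call is made from allele read counts: `NO_CALL` below `min_depth`
(default 5 reads), `HET` when the minor-allele read fraction reaches
`het_fraction` (default 0.25, read as minor-allele fraction), otherwise
homozygous for the majority allele. Multi-allelic sites are not modelled;
the simulator and readers are biallelic throughout.

Segmentation is run-based: within one chromosome, maximal stretches of
homozygous calls uninterrupted by a single `HET` call are reported when they
carry at least `min_markers` homozygous calls (default 25) and span at least
`min_span_bp` (default 1 Mb), bounded by the outermost homozygous markers of
the run. `NO_CALL` sites neither support nor interrupt a run. The defaults
are chosen so that exome-density markers (tens of markers per Mb) yield
megabase-scale segments while chance runs outside autozygosity (probability
~`(1 − het_rate)^25` per start) are vanishingly rare. The shared candidate
interval is the intersection of all affecteds' AOH covers minus the union of
the parents' covers, computed with exact 1-based inclusive interval
arithmetic (BED files on disk are 0-based half-open).

**Resolution.** A run-based mapper localizes an autozygosity breakpoint only
to between the last homozygous marker of the run and the first informative
(heterozygous) site beyond it; identity-by-state homozygosity extends every
called segment a geometrically distributed number of markers past the true
identity-by-descent boundary. Recovery tests therefore assert that a called
boundary lies between the true breakpoint and the first heterozygous-truth
marker outside it — the information-theoretic bound — rather than within one
marker spacing, and they require the causal locus inside the reported shared
interval in ≥ 99% of seeds: the causal site can fall in the inter-marker gap
at the very edge of a segment, and segments carrying fewer supporting
markers than `min_markers` (possible for ~2 Mb segments at the default
density of 2,000 markers per 150 Mb) are below the caller's detection limit
by construction.

## Variant filter funnel

The basic filters are conjunctive: `quality_pass` (an input flag; the
documented default rule in the simulator is adequate site depth in all
samples), a potentially deleterious consequence class (missense, nonsense,
stop loss, indel, or splice-region within ±5 bp of an exon), and rarity.
Rarity uses the *maximum* frequency across the population panels — the
strictest reading of "below threshold in every dataset" — with a < 1% bound
for novel variants and < 5% for variants already present in a curated
disease database (membership is an input flag; no licensed database is
bundled). Both bounds are strict inequalities.

Stage 1 keeps variants homozygous-alt in every affected and not
homozygous-alt in any healthy parent (a parent `NO_CALL` does not exclude).
Stage 2 keeps variants inside the linked region homozygous-alt in every
member of at least one affected family arm, rescuing variants that evaded
sequencing in the other arm (different capture platforms). The
compound-heterozygote scan pairs rare deleterious heterozygous variants of
one gene shared by all affecteds with trio-inferred opposite parental
origins; ambiguous origins exclude the pair (conservative).

## Pedigree likelihood and two-point LOD

The disease model is a penetrance triple for (AA, Aa, aa), default
(0, 0, 1): full penetrance, no phenocopies. The disease allele frequency
default is 0.05 (configurable); the marker allele frequency is user-supplied
or estimated from founder genotypes. Founders draw two-locus haplotypes at
Hardy–Weinberg and linkage equilibrium; transmission mixes parental
haplotypes at recombination fraction θ.

The likelihood is computed by sum-product elimination over each individual's
ordered two-locus genotype (16 states; phase is implicit in haplotype
order) — Elston–Stewart peeling — with greedy smallest-clique elimination
and per-step rescaling, so deep pedigrees cannot underflow; results are
returned as log10. Consanguineous loops are first broken by duplicating, per
independent loop, the deepest splittable individual (ties by id): the copy
takes over the spouse/children roles, and the likelihood sums over the
genotype shared by both copies (restricted to genotypes compatible with the
original's own data, which keeps the clamp space small in practice).
Monozygotic twin pairs are collapsed to one individual first, so a pair
counts as a single birth. Data impossible under the model yield −∞, not an
exception. `lod(θ) = log10 L(θ) − log10 L(0.5)`; the default grid is
{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}.

The engine is validated against an independent exhaustive-enumeration oracle
(depth-first search over all genotype assignments, valid on looped pedigrees
directly) on random pedigrees of up to 8 members at log10 tolerance 1e−9,
and against the closed form `lod(0) = m·log10 2` for m phase-known
fully informative non-recombinant meioses.

## Exome CNV calling

RPKM = reads / (exon length in kb) / (total mapped reads in millions); exon
length follows the same end − start convention as all intervals. The
deletion caller applies its criteria strictly in order: (1) candidate
entries have RPKM < 0.5; (2) common deletions are removed — the carrier
frequency at the exon among the *other* cohort samples must stay below 0.5%
(leave-one-out: a deletion private to one sample in a 200-sample cohort is
not evidence against itself), as are low-quality exons where ≥ 99% of
samples lack RPKM > 1; (3) candidates must overlap an AOH segment of the
same sample whose own span exceeds 0.5 Mb (the span qualifies the AOH
region, not the overlap); (4) candidates at consecutive exon indices of one
gene are merged; (5) samples with more than 10 merged calls are dropped
(the count refers to post-merge calls). The recorded cohort frequency of a
merged call is the maximum per-exon candidate fraction across its exons.

## Fine mapping

A SNP is informative when it is heterozygous in at least one obligate
carrier and both alleles are observed in the cohort — the purpose is to
distinguish the shared haplotype from the others segregating in the family.
Given a discordant unaffected homozygote with an informative recombination,
the minimum interval spans its heterozygous SNPs and the maximum interval
extends to the nearest flanking SNPs where it is homozygous for the
affecteds' shared allele, falling back to the region boundary when no such
SNP exists. Interval endpoints are the SNP positions themselves, inclusive;
missing genotypes are skipped when searching for flanks.

## Annotation arithmetic

Coding position 1 is the first base of the start codon, so the codon number
is `ceil(pos/3)`. A frameshift descriptor terminating at new-frame position
N appends N − 1 non-native residues. Hardy–Weinberg homozygote frequency is
q², reported alongside `round(1/q²/1e6)` as a "1 in N million" figure
(nearest-million rounding). Interval lengths are (end − start)/1e6, half-up
rounded to one decimal — the end − start convention is used everywhere
intervals are reported.

## Synthetic data generator

Gene dropping propagates founder haplotypes through the pedigree; each
meiosis is a two-state Markov switching process along the chromosome with
Haldane (no-interference) inter-site recombination fractions
`r = (1 − exp(−2d))/2`, where d is physical distance times a configurable
1 cM/Mb rate. An optional zero-recombination window emulates suppressed
recombination (MHC-like) and is off by default. Founder marker alleles are
i.i.d. at `marker_maf`; linkage disequilibrium is not modelled.

When the pedigree contains affected members the drop is conditioned on the
founder-mutation scenario: candidate disease-locus inheritance vectors are
rejection-sampled (vectorised in batches) until every affected is autozygous
for one target founder haplotype carrying the disease allele and nobody
marked unaffected is homozygous for it; marker transmission is then
simulated outward from the causal locus conditional on that vector, which
leaves the recombination process intact. Identity-by-descent labels per
individual and site give exact true autozygous segments. Unconditioned drops
(no affecteds) reproduce closed-form inbreeding: the genome fraction
autozygous in first-cousin offspring averages F = 1/16 over replicates.

Read-level calls use Poisson depth (default mean 40, comfortably above the
5-read call threshold) and binomial allele sampling at the base error rate
(default 0.005). The variant table embeds one causal variant — rare in every
panel, deleterious class, homozygous in affecteds, heterozygous in parents —
among 500 background variants with Hardy–Weinberg genotypes drawn from a
60/40 common/rare frequency mixture; a dropout option blanks the causal call
in one family arm to exercise the stage-2 rescue. RPKM matrices draw
per-exon baselines from U(20, 60) with log-normal noise (σ_log default 0.2)
and near-zero (U(0, 0.3)) deleted entries. All randomness flows from one
seed; identical seeds give byte-identical outputs.

The default study pedigree has two related family arms descending from one
ancestral couple, with three affected children of first-cousin unions and
six healthy parents, on a 150-Mb chromosome with 2,000 markers at minor
allele frequency 0.3 and the causal locus at 60 Mb. These sizes keep the
conditioned segment around the causal locus at the multi-megabase scale the
method targets while a full study simulates in well under a second.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, marker ascertainment and capture bias, mappability,
multi-allelic sites, genotyping error beyond binomial read sampling, sex
chromosomes, and phenocopies. Passing recovery tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to every artefact of real exome data.

## Validation problem sizes

The test suite runs ~100-seed batteries per stage: 100 simulated studies for
the filter funnel (with and without arm dropout), 100 for AOH recovery, 100
10-exon × 200-sample matrices for the deletion caller, 100 random pedigrees
(≤ 8 members, ~35% consanguineous) for likelihood-oracle agreement, and
10,000 gene-drop replicates for the F = 1/16 check. The full suite completes
in about a minute on one core.

## Known limitations

- Run-based AOH segmentation has no error tolerance inside a run: one
  spurious heterozygous call splits a segment. At default depth the
  per-site miscall probability is ~1e−13 for hom→het, so this is acceptable
  for exome depths; low-pass data would need an HMM caller (a non-goal).
- The likelihood engine is two-point only (no multipoint, no liability
  classes); loop clamping is exponential in the number of simultaneously
  broken loops, acceptable for family-study pedigrees where typed affecteds
  constrain the clamp space to a handful of states.
- The rarity filter's maximum-across-panels rule is one reading of
  "rare in every dataset"; per-panel alternatives would be laxer.
- The CNV caller targets homozygous/hemizygous deletions only; duplications
  and dosage models for heterozygous deletions are out of scope.
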