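# Methods

This document records the models, parameters, and numerical choices behind
each module, the scope of the synthetic generator, and the known limitations
of the detectors. Nothing here asserts an empirical result that is not
computed by the test suite or by `scripts/acceptance.py`.

## Folding engine (`g2lhe.fold`)

Secondary structure is computed by deterministic base-pair **maximization**
(Nussinov-style dynamic programming), not thermodynamics. The objective is
the number of nested pairs subject to:

* minimum helix length of 3 stacked pairs (`MIN_HELIX = 3`);
* minimum hairpin loop of 3 unpaired nucleotides (`MIN_LOOP = 3`);
* optional G·T wobble pairing (on by default);
* an optional `max_span` band that caps pair distance, keeping the DP
  O(n·span²) on long sequences;
* an optional *locality* objective that rewards long contiguous stacks over
  scattered pairs of equal count, used where a unique, register-stable
  traceback matters (helix tie-breaking).

Tracebacks are fully deterministic: ties are broken by fixed iteration order,
so the same sequence always yields the same pair list. Utility views —
`helices`, `unpaired_runs`, `top_level_subtrees`, `filter_helices`,
`long_stems`, `dot_bracket` — are pure functions of the pair list.

This choice trades thermodynamic realism for exact reproducibility and for
provable behavior on the designed synthetic sequences, whose stems are
constructed to be the unique pair-maximal structure.

## Synthetic generator (`g2lhe.synthetic`)

The generator is the ground-truth source for the whole pipeline. **Its
defaults are the study conditions**: the 13 family presets (five green-algal,
seven fungal, one bacterial) fix, per family, the structural subclass, the
domain V width (32 nt for *cox1*-874, otherwise 34 nt), the DIV–DV linker
motif (GGA for IIA1, TT for IIB1, AG for IIB2, A for IIC), the 5′ terminal
linker length ahead of the conserved GTGCG boundary, branch-point presence,
the EBS repertoire (EBS1/2/3 or EBS1/3), ORF placement (DIV, DIB, or DIII),
and the expected LAGLIDADG motif count (two, or one for the single-motif
families). Every record carries a `SyntheticTruth` with exact domain spans,
linker strings, EBS positions, and ORF coordinates, so detector accuracy is
measured against known truth rather than against another detector.

Designed stems are built so that pair maximization recovers the intended
register. In particular the DVI stem excludes T from the 5′ strand and
strengthens the nucleotides flanking the bulged adenosine, so the designed
branch-point bulge is the unique unpaired adenosine under the folding
objective (verified exhaustively across presets in the test suite).

`degrade_orf` injects exactly one of five lesions — `premature_stop`,
`frameshift`, `motif_loss`, `truncation`, `catalytic_disruption` — while
leaving the structural scaffold untouched.

`simulate_alignment` evolves sites independently down a Newick tree under
GTR(+I)(+Γ): per-site rates are drawn from the discrete-gamma/invariant
mixture, transition matrices come from the eigendecomposition of the
rate-normalized GTR generator, and the root state is drawn from the
stationary frequencies.

All randomness flows through `numpy.random.default_rng(seed)`; derived seeds
stay below 2³¹.

## Structure annotation (`g2lhe.structure`)

**Domain V detection** slides candidate windows of width 30–38 nt over the 3′
40% of the intron, folds each window (wobble on), and scores it by pair count
plus a bonus of 3 when an AGC/CGC trinucleotide (the catalytic-triad
signature) lies at the stem base. The best window must reach a paired
fraction ≥ 0.65; otherwise no DV is reported. The reported width is detected,
never assumed, which is what makes the 32 vs 34 nt family distinction a
measurement.

**De novo segmentation** (`segment_domains`) masks long ORFs (≥ 100 aa) to
keep the folder off coding sequence, anchors on the detected DV (DIV must end
within 12 nt of the DV window), and assigns DI–DIV from the top-level
subtrees of an anchored fold; DVI is the first stem 3′ of DV and is omitted
when nothing lies 3′ of DV. **Annotation-guided mode** takes domain spans as
given (from curated alignments or generator truth) and runs only the feature
detectors; it is the validated path (see Limitations).

**Terminal features**: the 5′ boundary motif GTGCG is matched with ≤ 1
mismatch within the leading region; the 5′ linker is the run preceding it.

**Branch point**: within DVI, the detector folds the domain and scans only
the true 3′ strand (strictly 3′ of the innermost pair) for an unpaired
adenosine bulge near the stem base; terminal-loop adenosines are therefore
not callable as branch points. Domains shorter than 10 nt are not scanned.

**EBS detection** reverse-complements the IBS sequences from the host flank
and searches the single-stranded loops of DI (EBS1/2) or the coordination
loop (EBS3). Sites of ≥ 4 nt may match anywhere exactly, or in loops with
wobble and ≤ 1 mismatch; sub-4-nt sites (EBS3) require a strict Watson–Crick
match confined to the coordination loop, since a 1-nt site would otherwise
match almost anywhere.

## Classification (`g2lhe.classify`)

`validate_intron` is the retention screen (boundary motif, DV presence,
length sanity); failures carry machine-readable reasons. `classify_subclass`
applies the established rule set in fixed order — IIA1: GGA linker plus
DII–DIII CRGA; IIB1: TT linker, DIa absent; IIB2: AG linker, DIa present;
IIC: single-A linker, IC2 absent — scoring each satisfied rule and refusing a
call (`unclassified`) below the minimum score, with a full `rule_trace` for
audit. Family assignment uses insertion site when available, else host gene
plus global-identity similarity to family medoids (Needleman–Wunsch identity
over the aligned length). `filter_homolog_hits` screens tabular homology
hits by length, identity, and coverage.

## ORF analysis (`g2lhe.orf`)

ORFs are discovered in all three forward frames under the mold-mitochondrial
genetic code (NCBI table 4, TGA = Trp) by default; GTG and ATG starts are
both accepted and both reported as M. Translation correctness is checked in
the tests against Biopython.

LAGLIDADG motifs are scored with a 10-column log-odds PWM (consensus
LAGLIDADGL) bundled as package data; a hit requires ≥ 60% of the consensus
self-score, and overlapping hits are resolved left-to-right. The rubric in
`score_degeneration` flags:

* `premature_stop` — in-frame stop before the expected terminus;
* `frameshift` — the anchor peptides of the two motif regions (or the
  C-terminal anchor WNKPQNSTHY for single-motif families) occur in different
  frames;
* `motif_loss` — fewer PWM hits than the family expects;
* `truncation` — ORF < 70% of the family median intact length (requires a
  supplied median);
* `catalytic_disruption` — the PWM-column-8 residue is not D/E.

Status is `intact_double` / `intact_single` / `degenerated`; intact records
carry no flags.

## Phylogenetics (`g2lhe.phylo`)

GTR+I+Γ likelihoods use the symmetrized eigendecomposition
Π^{1/2} Q Π^{−1/2} (real symmetric, stable eigenvectors), with the generator
normalized to mean rate 1 at stationarity. Discrete gamma uses Yang's
equal-probability categories with category means from the incomplete gamma
function; with `p_invariant` > 0 the variable-rate categories are jointly
rescaled by 1/(1−p_inv). Site likelihoods come from Felsenstein pruning over
a rooted view of the unrooted tree; correctness is proven in the tests
against explicit internal-state enumeration with `scipy.linalg.expm` on an
independently constructed generator, to 1e-8 per site, and against
closed-form Jukes–Cantor (nucleotide and 20-state) to 1e-10.

Branch lengths are optimized per edge by Brent's method on an exact
factorization of the edge likelihood (the per-site likelihood is affine in
the transition matrix of the focal edge), sweeping edges for a fixed number
of passes. Tree search is neighbor joining (JC distances) followed by NNI
hill-climbing; ≤ 8 leaves can be searched exhaustively. Monophyly
constraints are enforced structurally: the constrained search starts from a
tree with the taxon set grafted as a clade and rejects NNI moves that break
it. Protein models load from PAML-format matrices.

The SH test follows the standard recipe: per-topology site log-likelihood
rows, RELL bootstrap (10,000 replicates by default, vectorized in chunks),
per-replicate mean-centering, and p-values from the null distribution of the
centered maxima. Determinism is guaranteed by the seed.

Robinson–Foulds distances are computed from bipartition sets and verified
against dendropy.

## Reporting (`g2lhe.report`)

`feature_matrix` reports per-family proportions of the diagnostic features;
cells are proportions over members where the feature is callable, `NaN` when
uncallable for all members; `linker_motif` is agreement with the family's
modal linker string. `sequence_logo` computes per-position information
R = log₂|alphabet| − H with gaps excluded from frequencies but tracked as
occupancy (columns under 50% occupancy are flagged, never dropped); the
optional small-sample correction subtracts (s−1)/(2·ln2·n) and clamps at
zero. `motif_variant_proportions` tallies exact linker variants with rare
variants (< 1%) pooled as `other`. `load_census` returns the bundled
reference census (753 introns; 410/69/274 by ORF status; 78/613/62 by
lineage; a 100-sequence query panel) whose internal arithmetic is asserted
in the acceptance tests.

## Numerical and engineering choices

* One RNG family (`numpy.random.default_rng`) everywhere; no salted
  `hash()`; test seeds derive from CRC32 of string labels.
* Eigendecomposition over `expm` in the hot path; `expm` is reserved for
  oracles.
* RELL resampling is chunked to bound memory at 10,000 × n_sites.
* Banded folding keeps annotation linear-ish in sequence length for the
  ~900-nt synthetic introns.
* TSV/FASTA outputs have deterministic row and column order (byte-stable).

## Limitations

* **De novo segmentation is approximate.** DV detection itself is reliable
  (the acceptance suite measures ≥ 95% joint width-and-boundary recovery
  over 200 records), but full de novo DI–DVI segmentation recovers exact
  truth spans only part of the time;
  when top-level subtrees cannot be separated the annotator degrades
  gracefully to merged spans with `confidence` marked accordingly. The DIV
  3′ boundary can under-extend, leaving extra nucleotides in the apparent
  DIV–DV linker. Annotation-guided mode is the validated path for subclass
  calling and feature matrices.
* **EBS3 position is unidentifiable.** A 1-nt site has no unique placement;
  the detector reports presence in the coordination loop, not an exact span.
  Presence-level recovery is what the tests assert. EBS2-like matches can
  arise by chance in templates that genuinely lack EBS2; the de novo
  annotator therefore reports EBS calls as evidence, not truth.
* **Type-I calibration of the SH test** is demonstrated at a reduced scale
  (100 replicates of 300 sites, 2,000 RELL replicates, rejection rate ≤ 10%
  at α = 0.05) to fit the test-time budget; the SH test is conservative by
  construction, and the full-scale power result uses 2,000 sites and 10,000
  replicates.
* **The folder is not thermodynamic.** Structures are pair-maximal, which is
  correct by construction for the synthetic study system but would need
  replacement with a free-energy folder for natural sequences with
  non-canonical or pseudoknotted elements (pseudoknots are out of scope
  throughout).
* The genetic-code handling covers the standard and mold-mitochondrial
  tables via Biopython; other organellar codes work to the extent Biopython
  supports the table id.
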