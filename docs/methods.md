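# Methods

## Scope and data model

The package analyses multilocus microsatellite genotypes of individuals of
mixed ploidy (2x/3x/4x) in a complex of sexual diploids and apomictic
polyploids. All internal arithmetic is in **repeat units**; fragment sizes in
bp are converted on input via each locus's motif length and an optional
constant flanking offset (these constants are marker properties the user must
supply). An observed genotype at a locus is the set of **distinct** alleles:
peak profiles in polyploids do not resolve allele copy number, so dosage is
never represented or needed — every downstream method (Bruvo distance, MLG
identity, parentage matching) is defined on distinct-allele sets.

## Bruvo distance

Allele-pair distance: d(a, b) = 1 − 2^(−|a−b|), the geometric decay implied
by a stepwise mutation model (one repeat gained or lost per event). Locus
distance between equal-sized sets is the minimum over perfect matchings of
the mean pair distance; the assignment formulation is solved exactly by the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`), and an
exhaustive permutation path (`method="exact"`) exists purely as an
independent oracle — both are exact minima and are asserted equal over large
random samples in the tests.

Unequal set sizes (different ploidy, or unresolved dosage) are reconciled by
three models:

* **loss** — the smaller set is padded with virtual alleles at distance 1 to
  everything (the larger genotype's extra alleles are treated as later
  additions the smaller lineage never had);
* **addition** — the smaller set is padded with copies of its own alleles,
  the combination (searched exhaustively; the size difference here is ≤ 3)
  chosen to minimise the result;
* **combined** — the arithmetic mean of the two, the package default, for
  when the direction of ploidy change between the two genotypes is unknown.
  The choice is recorded in the pipeline manifest; loss and addition results
  differ only slightly on real mixed-ploidy pairs but the choice is exposed
  because it is not a neutral detail.

Genotype distance is the unweighted mean of locus distances over loci scored
in **both** individuals; loci missing in either are excluded rather than
imputed. Self-comparisons are included in histogram bookkeeping (an n-sample
matrix tallies n² ordered comparisons) but never in clustering.

## Clonal structure

* **MLGs**: connected components of the graph linking pairs at distance
  exactly 0 — any non-zero distance separates MLGs. One representative per
  MLG (lexicographically smallest sample id) feeds ordination, so clone
  abundance does not weight the axes.
* **Clone threshold**: the pairwise-distance histogram of a clonal complex
  is multimodal — a spike at ~0 (clone-mates ± somatic mutation and scoring
  error), then distinct sexual origins. The detector bins distances
  (default bin width 0.01, optional moving-average smoothing), takes the
  first local maximum from zero as the clone peak, and scans for the next
  local maximum whose intervening minimum falls below half the smaller
  flanking peak (the 0.5 prominence ratio stops count noise inside one mode
  from reading as a valley); the threshold is the centre of the
  minimum-count bin between the peaks, ties to the lower bin. A unimodal
  histogram yields no threshold and a warning — the caller must override
  manually, and the pipeline accepts such an override and logs it.
* **Lineages**: single-linkage connected components at d ≤ threshold —
  matching the transitive "clone-mate chain" semantics of clonal groups.
  Threshold 0 reduces exactly to MLG assignment, and partitions coarsen
  monotonically in the threshold.
* **Diversity**: 1 − λ with the unbiased estimator
  λ = Σ nᵢ(nᵢ−1)/(N(N−1)) over MLG sizes (the probability that two
  individuals drawn without replacement share an MLG); the biased plug-in
  Σ(nᵢ/N)² is available behind a flag for cross-checks only. Rarefied
  allelic richness subsamples without replacement (default 1000 replicates,
  seed mandatory) to compare taxa at a common sample size.

## Ordination and trees

PCoA is the eigendecomposition of the Gower-centred matrix −½ J D² J.
Coordinates are eigenvectors scaled by √eigenvalue for eigenvalues above a
relative tolerance; negative eigenvalues (Bruvo matrices are generally
non-Euclidean) are reported, not corrected, by default — percent variance is
quoted per positive axis of the positive total. Lingoes (constant added to
squared distances) and Cailliez (constant added to distances) corrections
are available as flags.

Neighbour joining is the Saitou–Nei agglomeration with the Q-criterion; ties
break deterministically to the lowest index pair. A negative limb length is
clamped to zero with the deficit moved to its sister limb, preserving the
cherry's span, so the method remains exactly consistent on additive
matrices (verified to 1e−9 against randomly generated additive trees, and
against scikit-bio's implementation). Output is an unrooted tree (trifurcating
root) written as newick with 6-decimal branch lengths.

## Parentage

Candidate pools per taxon: sexual outcrossers pool alleles over all samples
(their founding genotypes are assumed no longer sampled); apomicts are
represented by their majority MLG — the modal genotype, with a warning if it
covers ≤ 80 % of samples — optionally augmented with all minority variant
alleles for a second, more permissive pass (both passes are pipeline
stages). Designated hypervariable loci can be forced to contribute their
full variant set regardless of mode. The mismatch score of an unordered
candidate pair is the count, per allele over the configured loci, of target
alleles absent from the union of the two pools; zero means the pair could
have contributed everything. All pairs are reported ascending; ties share
rank 1. Self-pairs are excluded by default (flag to enable). No
gamete-ploidy feasibility filter is applied by default — matching is on
allele presence only.

Genome-specific loci (each tagged with the ancestral genome it amplifies
from) give a direct count of each genome's contribution in a hybrid: e.g. 2
alleles at the A-genome locus and 1 at the T-genome locus in a triploid
formed from a reduced tetraploid gamete and a reduced diploid gamete.

## Cytotype inference

Relative 2C (pg) = (sample peak / internal-standard peak) × standard 2C.
The continuous ploidy estimate p\* = 2 × 2C / 2C_diploid is called to the
nearest integer when within a tolerance (default 0.25), else flagged
ambiguous and excluded from summaries rather than forced. The default
tolerance reflects polyploid genome downsizing: empirically, tetraploids in
this kind of complex sit near p\* ≈ 3.8 rather than 4.0, so a tight
tolerance would reject real tetraploids while 0.25 still rejects midpoints.
Samples in the lower tail of a downsized tetraploid distribution can still
fall outside it and are then reported ambiguous — with heavy downsizing a
per-cytotype reference baseline is preferable to a single diploid ratio,
which is why the reference 2C is a config value rather than hard-coded.
Base chromosome number defaults to x = 17 (Maloideae).

## Synthetic data generator

The generator plants, by default: two sexual diploid taxa (13 A-genome and
33 T-genome samples) whose individuals draw ploidy alleles per locus
independently from truncated-geometric allele frequencies over 8–24 repeats
(13 loci, of which 3 amplify only in polyploids and 2 are genome-specific);
seven apomictic polyploid taxa totalling 161 samples (13/17/22+2/29/27/19/32)
— two founder tetraploids and five planted hybrids, including a triploid
from a reduced diploid egg × reduced tetraploid pollen (the "triploid
bridge") and two tetraploids from unreduced diploid × reduced tetraploid
gametes; and one taxon carrying a second planted lineage of two samples
(two independent sexual origins within one morphotaxon). Clone-mates copy
their founder and mutate per locus per step with probability 0.004 (±1
repeat, reflected at 1), keeping each taxon's modal MLG above 80 %
dominance while producing the rare stepwise variants that make threshold
detection meaningful. Gamete draws at genome-tagged loci are retried to
keep contributed alleles distinct, so genome-dosage counts equal the
planted gamete sizes. FCM records draw relative 2C from Gaussians at
planted means 1.63/2.33/3.07 pg (sd 0.018/0.022/0.084) — the 4x mean is
deliberately downsized below 2 × the diploid value.

What the generator does **not** emulate: scoring error and allele binning
artefacts, null alleles, population structure within sexual taxa, linkage,
facultative sexuality within apomicts, and homoplasy is only emergent (the
same repeat count reachable by different mutational paths), not modelled.
Passing recovery tests therefore shows the pipeline is correct under clean
stepwise-mutation clonality with well-separated origins; it does not show
robustness to genotyping noise or to overlapping distance modes, where the
manual threshold override exists.

## Numerical and design choices

* Matching enumeration is exact for allele sets ≤ 4 (tetraploid maximum);
  the assignment solver is the default path and must agree with enumeration
  (asserted over 10,000 random pairs in the acceptance suite).
* Distance matrices are validated (symmetry, zero diagonal, [0, 1]) at
  construction and on CSV read; round-trips are lossless to 9 decimals.
* All randomness flows through `numpy.random.default_rng` seeded from
  config; reruns with the same config are byte-identical.
* Pipeline analyses that mix diploids and polyploids use the core locus
  subset (loci amplifying in every taxon, inferred from the data unless
  configured); clone-threshold and lineage analyses use the full panel on
  polyploids only, and the diversity table carries one 1 − λ column per
  subset.
* Problem sizes in the test and acceptance runs (161-sample polyploid
  matrix, 200 random additive trees of 5–8 taxa, 100 threshold replicates,
  10,000 matching pairs) were chosen to exercise every code path at
  desk-scale while keeping a full run in tens of seconds.

## Known limitations

* Parentage scoring is presence-based: it cannot distinguish a true parent
  from any taxon whose pool happens to cover the target (high allele
  sharing produces zero-score ties, which are all reported).
* The valley detector assumes the clone peak is the mode nearest zero; a
  dataset dominated by singletons (mostly sexual) is unimodal away from
  zero and requires a manual threshold.
* Reduced gametes are only defined for even ploidies; triploid gamete
  production (unbalanced) is not simulated.
* One flow-cytometry reference baseline per run; mixed-standard designs
  need separate runs.
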