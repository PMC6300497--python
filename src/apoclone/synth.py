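"""Synthetic mixed-ploidy microsatellite data with known ground truth.

Emulates the statistical structure of a reticulate complex of apomictic
polyploids and their sexual diploid progenitors: two outcrossing diploid
taxa in which every individual is a unique multilocus genotype; several
polyploid apomictic taxa, each dominated by one clonal MLG plus rare
stepwise-mutation variants; high allele sharing across taxa because the
polyploids are planted hybrids whose gametes are drawn from simulated
parents; two genome-specific loci that amplify from only one ancestral
genome; and flow-cytometry peak summaries drawn around planted 2C means per
cytotype.

Every sample carries ground-truth labels (founder clone, lineage, mutation
count; true parent pair and gamete types for hybrids) so that recovery of
clone lineages, parentage and ploidy can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import Genotype, GenotypeSet, LocusDef
from .ploidy import FcmRecord

__all__ = [
    "LocusSim",
    "HybridOrigin",
    "TaxonSpec",
    "SimConfig",
    "Truth",
    "truncated_geometric_freqs",
    "simulate_sexual_population",
    "make_hybrid_founder",
    "propagate_apomictic_clone",
    "simulate_study",
    "study_config",
]


@dataclass(frozen=True)
class LocusSim:
    """Allele-frequency model for one locus: truncated geometric over a repeat range."""

    name: str
    support: tuple[int, ...]  # repeat counts
    freqs: tuple[float, ...]
    genome_tag: str = "none"
    core: bool = True  # amplifies in diploids as well as polyploids

    def __post_init__(self):
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies must sum to 1")
        if len(self.support) != len(self.freqs):
            raise ValueError(f"locus {self.name}: support/freqs length mismatch")


def truncated_geometric_freqs(lo: int = 8, hi: int = 24, q: float = 0.15
                              ) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Geometric allele frequencies over repeat counts ``lo..hi`` (heavier at lo)."""
    support = tuple(range(lo, hi + 1))
    w = np.array([(1 - q) ** i for i in range(len(support))])
    return support, tuple(w / w.sum())


@dataclass(frozen=True)
class HybridOrigin:
    """Planted hybridization event: parent taxa and gamete types.

    Gamete type ``"reduced"`` contributes ploidy/2 genome copies,
    ``"unreduced"`` the full ploidy (e.g. triploid = reduced diploid egg x
    reduced tetraploid pollen; tetraploid via unreduced diploid gamete).
    """

    parent_a: str
    parent_b: str
    gamete_a: str = "reduced"
    gamete_b: str = "reduced"

    def gamete_size(self, which: str, parent_ploidy: int) -> int:
        g = self.gamete_a if which == "a" else self.gamete_b
        if g == "reduced":
            if parent_ploidy % 2:
                raise ValueError(
                    f"reduced gamete from odd ploidy {parent_ploidy} is not supported"
                )
            return parent_ploidy // 2
        if g == "unreduced":
            return parent_ploidy
        raise ValueError(f"gamete type must be 'reduced' or 'unreduced', got {g!r}")


@dataclass
class TaxonSpec:
    """One simulated taxon (or planted lineage within a taxon).

    ``genomes`` lists the ancestral genome tags this taxon carries; a
    genome-specific locus amplifies only in taxa carrying its genome.  For
    hybrids the carried genomes are the union of the parents' and need not
    be given.  ``lineage`` defaults to ``name``; a second entry with the
    same ``name`` but a different ``lineage`` plants an extra clonal lineage
    inside one taxon.
    """

    name: str
    breeding: str  # "sexual" | "apomictic"
    ploidy: int
    n_samples: int
    origin: HybridOrigin | None = None  # None = founder drawn from frequencies
    genomes: tuple[str, ...] = ()
    mutation_rate: float = 0.004  # per locus per propagation step
    n_mutation_steps: int = 1
    lineage: str = ""

    def __post_init__(self):
        if self.breeding not in ("sexual", "apomictic"):
            raise ValueError("breeding must be 'sexual' or 'apomictic'")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not self.lineage:
            self.lineage = self.name


@dataclass
class SimConfig:
    loci: list[LocusSim]
    taxa: list[TaxonSpec]
    seed: int = 0
    fcm_2c_means: dict[int, float] = field(
        default_factory=lambda: {2: 1.63, 3: 2.33, 4: 3.07}
    )
    fcm_2c_sd: dict[int, float] = field(
        default_factory=lambda: {2: 0.018, 3: 0.022, 4: 0.084}
    )
    fcm_cv_mean: float = 2.5
    fcm_cv_sd: float = 0.4
    standard_peak: float = 100.0
    standard_2c: float = 1.0

    def panel(self) -> list[LocusDef]:
        return [LocusDef(l.name, repeat_len=2, genome_tag=l.genome_tag) for l in self.loci]


@dataclass
class Truth:
    """Ground-truth labels emitted alongside the synthetic dataset."""

    founder_of: dict[str, str] = field(default_factory=dict)  # sample -> lineage id
    mutations_of: dict[str, int] = field(default_factory=dict)
    parent_pair_of: dict[str, tuple[str, str]] = field(default_factory=dict)
    gametes_of: dict[str, tuple[str, str]] = field(default_factory=dict)
    tagged_counts_of: dict[str, dict[str, int]] = field(default_factory=dict)
    ploidy_of: dict[str, int] = field(default_factory=dict)
    planted_2c: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "founder_of": self.founder_of,
            "mutations_of": self.mutations_of,
            "parent_pair_of": {k: list(v) for k, v in self.parent_pair_of.items()},
            "gametes_of": {k: list(v) for k, v in self.gametes_of.items()},
            "tagged_counts_of": self.tagged_counts_of,
            "ploidy_of": self.ploidy_of,
            "planted_2c": self.planted_2c,
        }


# ---------------------------------------------------------------------------
# primitive generators (operate on per-locus allele dicts)


def _draw_alleles(locus: LocusSim, k: int, rng: np.random.Generator,
                  *, distinct: bool = False) -> frozenset[int]:
    support = np.array(locus.support)
    p = np.array(locus.freqs)
    if distinct and k <= len(support):
        picks = rng.choice(support, size=k, replace=False, p=p)
    else:
        picks = rng.choice(support, size=k, replace=True, p=p)
    return frozenset(int(x) for x in picks)


def simulate_sexual_population(
    loci: list[LocusSim],
    n: int,
    ploidy: int = 2,
    seed: int | np.random.Generator = 0,
    *,
    genomes: tuple[str, ...] = ("genomeA", "genomeB"),
) -> list[dict[str, frozenset[int]]]:
    """Independent random-mating draws: each individual samples ``ploidy``
    alleles per locus from the locus frequencies.

    Loci tagged for a genome the population does not carry come back empty
    (failed amplification).  With many alleles per locus, every individual
    is a distinct multilocus genotype with overwhelming probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        g: dict[str, frozenset[int]] = {}
        for loc in loci:
            if loc.genome_tag != "none" and loc.genome_tag not in genomes:
                g[loc.name] = frozenset()
            else:
                g[loc.name] = _draw_alleles(loc, ploidy, rng)
        out.append(g)
    return out


def _gamete(alleles: frozenset[int], size: int, rng: np.random.Generator) -> list[int]:
    """Sample ``size`` allele copies from a parent's distinct allele set."""
    pool = sorted(alleles)
    if not pool:
        return []
    if size <= len(pool):
        picks = rng.choice(len(pool), size=size, replace=False)
    else:
        picks = np.concatenate(
            [np.arange(len(pool)), rng.choice(len(pool), size=size - len(pool))]
        )
    return [pool[i] for i in picks]


def make_hybrid_founder(
    parent_a: dict[str, frozenset[int]],
    parent_b: dict[str, frozenset[int]],
    size_a: int,
    size_b: int,
    loci: list[LocusSim],
    seed: int | np.random.Generator = 0,
    *,
    distinct_at_tagged: bool = True,
) -> tuple[dict[str, frozenset[int]], dict[str, int]]:
    """Fuse two gametes into a hybrid founder genotype.

    Per locus, ``size_a`` allele copies are sampled from parent A's observed
    alleles and ``size_b`` from parent B's; the child's observed set is their
    union, so at mutation rate zero every child allele is present in a
    parent.  At genome-tagged loci the draw is retried a bounded number of
    times to keep the contributed alleles distinct (such loci are highly
    polymorphic, and distinct contributions are what make genome-dosage
    counting informative); parents that do not amplify a tagged locus
    contribute nothing there.

    Returns the allele dict and, per tagged locus, the planted count of
    distinct observed alleles.
    """
    if size_a < 1 or size_b < 1:
        raise ValueError("gamete sizes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    child: dict[str, frozenset[int]] = {}
    tagged_counts: dict[str, int] = {}
    for loc in loci:
        a_all = parent_a.get(loc.name, frozenset())
        b_all = parent_b.get(loc.name, frozenset())
        tries = 100 if (distinct_at_tagged and loc.genome_tag != "none") else 1
        best: list[int] = []
        want = (size_a if a_all else 0) + (size_b if b_all else 0)
        for _ in range(tries):
            ga = _gamete(a_all, size_a, rng) if a_all else []
            gb = _gamete(b_all, size_b, rng) if b_all else []
            combo = ga + gb
            if len(set(combo)) > len(set(best)):
                best = combo
            if len(set(best)) == want:
                break
        child[loc.name] = frozenset(best)
        if loc.genome_tag != "none":
            tagged_counts[loc.name] = len(child[loc.name])
    return child, tagged_counts


def propagate_apomictic_clone(
    founder: dict[str, frozenset[int]],
    n: int,
    mutation_rate: float,
    n_steps: int = 1,
    seed: int | np.random.Generator = 0,
) -> tuple[list[dict[str, frozenset[int]]], list[int]]:
    """Clonal (apomictic) copies of a founder with stepwise somatic mutation.

    Each of the ``n`` samples copies the founder, then per locus per step
    mutates with probability ``mutation_rate``: one allele shifts by +/-1
    repeat with equal probability (reflected at 1).  Returns the genotypes
    and the per-sample mutation counts.
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out, counts = [], []
    loci = sorted(founder)
    for _ in range(n):
        g = {l: founder[l] for l in founder}
        k = 0
        for _step in range(n_steps):
            for l in loci:
                obs = g[l]
                if not obs:
                    continue
                if rng.random() < mutation_rate:
                    allele = sorted(obs)[rng.integers(len(obs))]
                    step = 1 if allele <= 1 else int(rng.choice([-1, 1]))
                    g[l] = (obs - {allele}) | {allele + step}
                    k += 1
        out.append(g)
        counts.append(k)
    return out, counts


# ---------------------------------------------------------------------------
# full-study composition


def study_config(seed: int = 0) -> SimConfig:
    """Default configuration mirroring the structure of a nine-taxon complex.

    Two sexual diploids (an A-genome taxon, n=13, and a T-genome taxon,
    n=33), plus seven apomictic polyploid taxa totalling 161 samples: two
    founder tetraploids in the A-genome subgenus and five planted hybrids —
    including one triploid formed from a reduced diploid egg and reduced
    tetraploid pollen (2:1 genome-tagged allele ratio) and two tetraploids
    from unreduced diploid x reduced tetraploid gametes (2:2 ratio).  One
    taxon carries a second planted lineage of two samples, so clone-lineage
    detection should find two sexual origins within it.  13 loci, of which
    10 amplify in the diploids; allele frequencies truncated-geometric over
    8-24 repeats.
    """
    loci: list[LocusSim] = []
    qs = [0.12, 0.15, 0.18, 0.2, 0.22, 0.25, 0.14, 0.16, 0.19, 0.21, 0.13, 0.17, 0.23]
    specs = [
        ("GS_A", "genomeA", True),
        ("GS_B", "genomeB", True),
    ] + [(f"SSR{i:02d}", "none", i <= 8) for i in range(1, 12)]
    for (name, tag, core), q in zip(specs, qs):
        support, freqs = truncated_geometric_freqs(8, 24, q)
        loci.append(LocusSim(name, support, freqs, genome_tag=tag, core=core))
    taxa = [
        TaxonSpec("aria_like", "sexual", 2, 13, genomes=("genomeA",)),
        TaxonSpec("torminalis_like", "sexual", 2, 33, genomes=("genomeB",)),
        TaxonSpec("rupicola_like", "apomictic", 4, 13, genomes=("genomeA",)),
        TaxonSpec("porrigentiformis_like", "apomictic", 4, 17, genomes=("genomeA",)),
        TaxonSpec(
            "vexans_like", "apomictic", 4, 22,
            origin=HybridOrigin("aria_like", "rupicola_like", "unreduced", "reduced"),
        ),
        TaxonSpec(
            "margaretae_like", "apomictic", 4, 29,
            origin=HybridOrigin("vexans_like", "rupicola_like", "reduced", "reduced"),
        ),
        TaxonSpec(
            "subcuneata_like", "apomictic", 3, 27,
            origin=HybridOrigin("torminalis_like", "margaretae_like", "reduced", "reduced"),
        ),
        TaxonSpec(
            "admonitor_like", "apomictic", 4, 19,
            origin=HybridOrigin("torminalis_like", "margaretae_like", "unreduced", "reduced"),
        ),
        TaxonSpec(
            "devoniensis_like", "apomictic", 4, 32,
            origin=HybridOrigin("torminalis_like", "margaretae_like", "unreduced", "reduced"),
        ),
        TaxonSpec(
            "vexans_like", "apomictic", 4, 2, lineage="vexans_like_2",
            origin=HybridOrigin("vexans_like", "margaretae_like", "reduced", "reduced"),
        ),
    ]
    return SimConfig(loci=loci, taxa=taxa, seed=seed)


def _mask_noncore(alleles: dict[str, frozenset[int]], loci: list[LocusSim]
                  ) -> dict[str, frozenset[int]]:
    """Diploid view of a genotype: polyploid-only loci fail to amplify."""
    return {
        l.name: (alleles.get(l.name, frozenset()) if l.core else frozenset())
        for l in loci
    }


def simulate_study(config: SimConfig | None = None, seed: int | None = None
                   ) -> tuple[GenotypeSet, list[FcmRecord], Truth]:
    """Generate the full synthetic dataset: genotypes, FCM peaks, and truth.

    Taxa are generated in config order; hybrid origins may reference any
    earlier taxon (sexual parents contribute a heterozygous individual's
    gamete; apomictic parents contribute gametes from their founder MLG).
    """
    cfg = config or study_config()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.loci
    truth = Truth()
    genotypes: list[Genotype] = []
    # full (unmasked) allele profiles available as gamete sources
    sexual_pool: dict[str, list[dict[str, frozenset[int]]]] = {}
    founder_of_taxon: dict[str, dict[str, frozenset[int]]] = {}
    counter = 0

    def pick_parent_source(name: str) -> dict[str, frozenset[int]]:
        if name in founder_of_taxon:
            return founder_of_taxon[name]
        candidates = sexual_pool[name]
        # prefer a parent heterozygous at every tagged locus it amplifies
        order = rng.permutation(len(candidates))
        for i in order:
            cand = candidates[i]
            if all(
                len(cand.get(l.name, frozenset())) != 1
                for l in loci
                if l.genome_tag != "none"
            ):
                return cand
        return candidates[order[0]]

    for spec in cfg.taxa:
        if spec.breeding == "sexual":
            full = simulate_sexual_population(
                loci, spec.n_samples, spec.ploidy, rng, genomes=spec.genomes
            )
            sexual_pool[spec.name] = full
            for alleles in full:
                counter += 1
                sid = f"{spec.name}_{counter:03d}"
                genotypes.append(
                    Genotype(sid, spec.name, "site1", spec.ploidy,
                             _mask_noncore(alleles, loci))
                )
                truth.founder_of[sid] = sid  # every sexual sample its own origin
                truth.mutations_of[sid] = 0
                truth.ploidy_of[sid] = spec.ploidy
            continue

        # apomictic: build or inherit the founder genotype
        if spec.origin is None:
            founder: dict[str, frozenset[int]] = {}
            for loc in loci:
                if loc.genome_tag != "none" and loc.genome_tag not in spec.genomes:
                    founder[loc.name] = frozenset()
                else:
                    founder[loc.name] = _draw_alleles(loc, spec.ploidy, rng, distinct=True)
            tagged_counts = {
                l.name: len(founder[l.name]) for l in loci if l.genome_tag != "none"
            }
        else:
            pa = pick_parent_source(spec.origin.parent_a)
            pb = pick_parent_source(spec.origin.parent_b)
            ploidy_a = next(
                t.ploidy for t in cfg.taxa if t.name == spec.origin.parent_a
            )
            ploidy_b = next(
                t.ploidy for t in cfg.taxa if t.name == spec.origin.parent_b
            )
            sa = spec.origin.gamete_size("a", ploidy_a)
            sb = spec.origin.gamete_size("b", ploidy_b)
            if sa + sb != spec.ploidy:
                raise ValueError(
                    f"taxon {spec.lineage}: gamete sizes {sa}+{sb} != ploidy {spec.ploidy}"
                )
            founder, tagged_counts = make_hybrid_founder(pa, pb, sa, sb, loci, rng)
            truth.parent_pair_of[spec.lineage] = (
                spec.origin.parent_a,
                spec.origin.parent_b,
            )
            truth.gametes_of[spec.lineage] = (spec.origin.gamete_a, spec.origin.gamete_b)
        if spec.lineage == spec.name:  # primary lineage defines the taxon founder
            founder_of_taxon.setdefault(spec.name, founder)
        truth.tagged_counts_of[spec.lineage] = tagged_counts

        samples, mut_counts = propagate_apomictic_clone(
            founder, spec.n_samples, spec.mutation_rate, spec.n_mutation_steps, rng
        )
        for alleles, k in zip(samples, mut_counts):
            counter += 1
            sid = f"{spec.name}_{counter:03d}"
            genotypes.append(Genotype(sid, spec.name, "site1", spec.ploidy, dict(alleles)))
            truth.founder_of[sid] = spec.lineage
            truth.mutations_of[sid] = k
            truth.ploidy_of[sid] = spec.ploidy

    gs = GenotypeSet(cfg.panel(), genotypes)

    # flow-cytometry peak summaries around planted per-cytotype 2C means
    fcm: list[FcmRecord] = []
    for g in genotypes:
        p = truth.ploidy_of[g.sample_id]
        mean = cfg.fcm_2c_means[p]
        sd = cfg.fcm_2c_sd[p]
        rel2c = float(rng.normal(mean, sd))
        truth.planted_2c[g.sample_id] = rel2c
        fcm.append(
            FcmRecord(
                sample_id=g.sample_id,
                sample_peak=rel2c * cfg.standard_peak / cfg.standard_2c,
                standard_peak=cfg.standard_peak,
                standard_2c=cfg.standard_2c,
                cv_percent=float(max(0.5, rng.normal(cfg.fcm_cv_mean, cfg.fcm_cv_sd))),
                taxon=g.taxon,
            )
        )
    return gs, fcm, truth


def core_loci(cfg: SimConfig) -> list[str]:
    """Names of the loci that amplify in diploids as well as polyploids."""
    return [l.name for l in cfg.loci if l.core]


def polyploid_loci(cfg: SimConfig) -> list[str]:
    """All locus names (the full panel used for polyploid-only analyses)."""
    return [l.name for l in cfg.loci]
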