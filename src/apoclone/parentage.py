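"""Exhaustive hybrid-parentage scoring by allele matching.

For a putative allopolyploid, every unordered pair of candidate parental
taxa is scored by counting the target's alleles that are absent from the
union of the two candidates' allele pools, locus by locus.  A score of zero
means the pair could jointly have contributed every allele — a potential
hybrid match; non-zero scores rank "next best" pairs.

Pool construction follows how each taxon reproduces: sexual outcrossers pool
alleles over *all* their samples (the founding genotype itself is presumed
gone), whereas apomicts are represented by the majority multilocus genotype
(the clone carried by >80% of individuals), optionally augmented with the
minority mutational variants for a second, more permissive pass.

Genome-specific loci (amplifying from only one ancestral genome) let the two
parental genome contributions be counted directly in a hybrid, e.g. a 2:1
allele ratio for a triploid formed from an unreduced-vs-reduced gamete pair.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import pandas as pd

from .genotype_io import Genotype, GenotypeSet

__all__ = [
    "AllelePool",
    "majority_genotype",
    "build_pool",
    "pair_mismatch_score",
    "rank_parent_pairs",
    "genome_specific_contribution",
]

POOL_SOURCES = ("majority_mlg", "all_samples", "majority_plus_minority")


@dataclass
class AllelePool:
    """Per-locus sets of candidate parental alleles for one taxon."""

    taxon: str
    alleles: dict[str, frozenset[int]]
    source: str = "all_samples"

    def at(self, locus: str) -> frozenset[int]:
        return self.alleles.get(locus, frozenset())


def majority_genotype(gs: GenotypeSet, taxon: str,
                      *, dominance: float = 0.8) -> Genotype:
    """Modal multilocus genotype of a (presumed apomictic) taxon.

    Warns when the modal MLG covers <= ``dominance`` of samples (the
    majority-genotype representation is then questionable) and when the mode
    is tied; ties break to the lexicographically first carrier's genotype.
    """
    sub = gs.subset_taxa([taxon])
    if not sub.genotypes:
        raise ValueError(f"no samples for taxon {taxon!r}")
    loci = sub.locus_names
    keys = Counter(g.mlg_key(loci) for g in sub.genotypes)
    top = max(keys.values())
    modal_keys = [k for k, c in keys.items() if c == top]
    if len(modal_keys) > 1:
        warnings.warn(f"taxon {taxon!r}: modal MLG tied ({len(modal_keys)} ways); "
                      "picking the first carrier by sample id", stacklevel=2)
    carriers = sorted(
        g.sample_id for g in sub.genotypes if keys[g.mlg_key(loci)] == top
    )
    chosen = sub.by_id(carriers[0])
    frac = top / len(sub.genotypes)
    if frac <= dominance:
        warnings.warn(
            f"taxon {taxon!r}: modal MLG covers only {frac:.0%} of samples "
            f"(<= {dominance:.0%})", stacklevel=2,
        )
    return chosen


def build_pool(gs: GenotypeSet, taxon: str, source: str = "all_samples",
               *, variable_loci: tuple[str, ...] = ()) -> AllelePool:
    """Construct a candidate-parent allele pool.

    ``source="all_samples"`` unions alleles over every sample (sexual taxa);
    ``"majority_mlg"`` uses only the modal MLG (apomicts);
    ``"majority_plus_minority"`` unions the modal MLG with every minority
    variant allele.  ``variable_loci`` names loci (e.g. hypervariable
    dinucleotide markers) whose full observed variant set is always pooled
    regardless of source.
    """
    if source not in POOL_SOURCES:
        raise ValueError(f"source must be one of {POOL_SOURCES}")
    sub = gs.subset_taxa([taxon])
    if not sub.genotypes:
        raise ValueError(f"no samples for taxon {taxon!r}")
    all_union: dict[str, frozenset[int]] = {}
    for l in sub.locus_names:
        u: frozenset[int] = frozenset()
        for g in sub.genotypes:
            u |= g.alleles.get(l, frozenset())
        all_union[l] = u
    if source in ("all_samples", "majority_plus_minority"):
        pool = dict(all_union)
    else:
        maj = majority_genotype(gs, taxon)
        pool = {l: maj.alleles.get(l, frozenset()) for l in sub.locus_names}
        for l in variable_loci:
            if l in all_union:
                pool[l] = all_union[l]
    return AllelePool(taxon, pool, source)


def pair_mismatch_score(
    target: Genotype,
    pool_a: AllelePool,
    pool_b: AllelePool,
    loci: list[str],
) -> int:
    """Count of target alleles absent from the union of two parental pools.

    Counted per allele over ``loci`` scored in the target: a locus with two
    uncovered alleles contributes 2.  A locus absent from both pools counts
    every target allele there as missing (logged as a warning).  Zero means
    the pair jointly covers the target — a potential hybrid match.
    """
    score = 0
    for l in loci:
        obs = target.alleles.get(l, frozenset())
        if not obs:
            continue
        union = pool_a.at(l) | pool_b.at(l)
        if not union:
            warnings.warn(
                f"locus {l} absent from pools {pool_a.taxon!r} and "
                f"{pool_b.taxon!r}; all {len(obs)} target alleles count as missing",
                stacklevel=2,
            )
        score += len(obs - union)
    return score


def rank_parent_pairs(
    target: Genotype,
    pools: dict[str, AllelePool],
    loci: list[str],
    *,
    allow_self_pairs: bool = False,
) -> pd.DataFrame:
    """Score every unordered candidate pair against a target genotype.

    Returns a DataFrame (parent_a, parent_b, mismatches, rank) sorted
    ascending by mismatch count; all best-score ties share rank 1.  With
    ``allow_self_pairs`` a taxon may appear as both parents (selfing or
    autopolyploid origin).
    """
    names = sorted(pools)
    if len(names) < 2 and not allow_self_pairs:
        raise ValueError("need at least 2 candidate taxa")
    combos = (
        combinations_with_replacement(names, 2)
        if allow_self_pairs
        else combinations(names, 2)
    )
    rows = []
    for a, b in combos:
        rows.append(
            {
                "parent_a": a,
                "parent_b": b,
                "mismatches": pair_mismatch_score(target, pools[a], pools[b], loci),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mismatches", "parent_a", "parent_b"], ignore_index=True
    )
    df["rank"] = df["mismatches"].rank(method="min").astype(int)
    return df


@dataclass
class GenomeContribution:
    """Observed allele counts at genome-tagged loci plus the ratio string."""

    counts: dict[str, int]  # genome tag -> distinct allele count
    loci: dict[str, str]  # locus name -> genome tag
    missing: list[str] = field(default_factory=list)

    @property
    def ratio(self) -> str:
        tags = sorted(self.counts)
        return ":".join(str(self.counts[t]) for t in tags)


def genome_specific_contribution(target: Genotype, panel) -> GenomeContribution:
    """Count alleles at genome-specific loci to apportion parental genomes.

    For each locus tagged ``genomeA`` or ``genomeB`` in the panel, counts the
    target's distinct observed alleles; a tagged locus that failed to amplify
    contributes 0 and is flagged as missing.  The ratio string (tags in
    alphabetical order, e.g. ``"2:1"`` for genomeA:genomeB) summarises the
    inferred contribution of each ancestral genome.
    """
    tagged = [l for l in panel if l.genome_tag != "none"]
    if not tagged:
        raise ValueError("panel declares no genome-tagged locus")
    counts: dict[str, int] = {}
    loci: dict[str, str] = {}
    missing: list[str] = []
    for l in tagged:
        obs = target.alleles.get(l.name, frozenset())
        counts[l.genome_tag] = counts.get(l.genome_tag, 0) + len(obs)
        loci[l.name] = l.genome_tag
        if not obs:
            missing.append(l.name)
    return GenomeContribution(counts, loci, missing)
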