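"""Bruvo genetic distance for microsatellite genotypes of equal or unequal ploidy.

The stepwise-mutation distance between two alleles with repeat counts ``a``
and ``b`` is ``1 - 2**(-|a - b|)``: zero for identical alleles, approaching 1
as the repeat difference grows.  A locus distance between two allele sets is
the minimum, over all ways of pairing the alleles one-to-one, of the mean
allele-pair distance.  When the two sets differ in size (different ploidy, or
unresolved dosage), the smaller set is padded with *virtual* alleles under one
of two genome models:

``loss``
    the larger genotype is assumed to derive from a higher-ploidy ancestor
    that lost alleles; virtual alleles are "infinitely distant" (distance 1 to
    every real allele).
``addition``
    the smaller genotype is assumed to have gained duplicated copies of its
    own alleles; the padding copies are chosen (exhaustively) to minimise the
    resulting distance.
``combined``
    the arithmetic mean of the loss and addition results — appropriate when
    neither direction of ploidy change can be assumed, and the default here.

A genotype distance is the unweighted mean of locus distances over loci
scored in both individuals.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import DistanceMatrix, Genotype, GenotypeSet

__all__ = [
    "INTER_PLOIDY_MODELS",
    "allele_pair_distance",
    "locus_distance",
    "genotype_distance",
    "distance_matrix",
]

INTER_PLOIDY_MODELS = ("loss", "addition", "combined")

#: virtual-allele sentinel used by the loss model (distance 1 to everything)
_VIRTUAL = None


def allele_pair_distance(a: int, b: int) -> float:
    """Stepwise-mutation distance ``1 - 2**(-|a-b|)`` between two repeat counts."""
    if a <= 0 or b <= 0:
        raise ValueError("repeat counts must be positive")
    return 1.0 - 2.0 ** (-abs(int(a) - int(b)))


def _cost_matrix(xs: list, ys: list) -> np.ndarray:
    """Pairwise allele distances; the ``None`` sentinel is distance 1 to all."""
    m = np.empty((len(xs), len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            m[i, j] = 1.0 if (x is _VIRTUAL or y is _VIRTUAL) else allele_pair_distance(x, y)
    return m


def _min_matching(cost: np.ndarray, method: str) -> float:
    """Minimum mean cost over perfect matchings of a square cost matrix."""
    n = cost.shape[0]
    if method == "exact":
        best = min(sum(cost[i, p[i]] for i in range(n)) for p in permutations(range(n)))
        return best / n
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum()) / n


def locus_distance(
    alleles_a,
    alleles_b,
    model: str = "combined",
    *,
    method: str = "lsa",
) -> float:
    """Bruvo distance between two allele sets at one locus.

    Parameters
    ----------
    alleles_a, alleles_b : iterable of int
        Distinct observed repeat counts; both must be non-empty (a missing
        locus is the caller's concern).
    model : {"loss", "addition", "combined"}
        How to reconcile sets of unequal size.
    method : {"lsa", "exact"}
        Matching minimisation: Hungarian assignment (default) or exhaustive
        permutation enumeration.  Both are exact minima; ``exact`` exists as
        an independent oracle for the assignment path.
    """
    a = sorted(alleles_a)
    b = sorted(alleles_b)
    if not a or not b:
        raise ValueError("locus_distance requires non-empty allele sets")
    if model not in INTER_PLOIDY_MODELS:
        raise ValueError(f"model must be one of {INTER_PLOIDY_MODELS}")
    if len(a) == len(b):
        return _min_matching(_cost_matrix(a, b), method)
    small, large = (a, b) if len(a) < len(b) else (b, a)
    k = len(large) - len(small)

    def loss() -> float:
        padded = small + [_VIRTUAL] * k
        return _min_matching(_cost_matrix(padded, large), method)

    def addition() -> float:
        best = np.inf
        for extra in combinations_with_replacement(sorted(set(small)), k):
            padded = small + list(extra)
            best = min(best, _min_matching(_cost_matrix(padded, large), method))
        return best

    if model == "loss":
        return loss()
    if model == "addition":
        return addition()
    return (loss() + addition()) / 2.0


def genotype_distance(
    ga: Genotype,
    gb: Genotype,
    model: str = "combined",
    *,
    loci: list[str] | None = None,
    method: str = "lsa",
) -> float:
    """Mean Bruvo locus distance over loci scored in both genotypes.

    Loci missing (unscored) in either individual are excluded from the mean;
    if no locus is scored in both, a ``ValueError`` is raised.
    """
    if loci is None:
        loci = sorted(set(ga.alleles) | set(gb.alleles))
    shared = [
        l for l in loci if ga.alleles.get(l) and gb.alleles.get(l)
    ]
    if not shared:
        raise ValueError(
            f"no shared scored locus between {ga.sample_id} and {gb.sample_id}"
        )
    total = 0.0
    for l in shared:
        total += locus_distance(ga.alleles[l], gb.alleles[l], model, method=method)
    return total / len(shared)


def distance_matrix(
    gs: GenotypeSet,
    model: str = "combined",
    *,
    loci: list[str] | None = None,
    method: str = "lsa",
) -> DistanceMatrix:
    """Pairwise Bruvo distances over all genotypes in ``gs``.

    Computes the n(n-1)/2 unordered pairs; the result is symmetric with a
    zero diagonal.
    """
    gts = gs.genotypes
    if len(gts) < 2:
        raise ValueError("need at least 2 genotypes")
    if loci is None:
        loci = gs.locus_names
    n = len(gts)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = genotype_distance(gts[i], gts[j], model, loci=loci, method=method)
            except ValueError as e:
                raise ValueError(
                    f"distance failed for pair ({gts[i].sample_id}, "
                    f"{gts[j].sample_id}): {e}"
                ) from e
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(gs.sample_ids, vals)
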