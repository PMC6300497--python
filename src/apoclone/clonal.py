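"""Clone detection and genotypic diversity for predominantly apomictic taxa.

Individuals with identical multilocus genotypes (MLGs) — zero pairwise
distance — are clone-mates.  MLGs that differ only by somatic stepwise
mutation cluster below a small genetic distance, while MLGs arising from
separate sexual events sit much further apart; the pairwise-distance
histogram is therefore typically multimodal, with a peak at zero (clone-mates
plus scoring noise), a valley, and further peaks for distinct clones.  The
valley position is the natural threshold for grouping MLGs into *clonal
lineages*, each representing a single sexual origin.

Diversity is summarised per taxon as: sample count N, distinct-allele count
A, MLG count Ng, the complement of Simpson's concentration (1 - lambda, the
probability that two individuals drawn without replacement carry different
MLGs), and the clonal-lineage count Nc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import DistanceMatrix, GenotypeSet

__all__ = [
    "Partition",
    "DistanceHistogram",
    "assign_mlgs",
    "assign_clonal_lineages",
    "histogram_and_threshold",
    "simpson_complement",
    "allele_richness",
    "rarefied_richness",
    "diversity_table",
]


@dataclass
class Partition:
    """Disjoint, exhaustive grouping of samples with the threshold that made it."""

    group_of: dict[str, int]
    threshold: float = 0.0
    representatives: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for g in self.group_of.values():
            counts[g] = counts.get(g, 0) + 1
        return [counts[k] for k in sorted(counts)]

    def members(self, group: int) -> list[str]:
        return sorted(s for s, g in self.group_of.items() if g == group)

    def restrict(self, sample_ids: list[str]) -> "Partition":
        """Sub-partition over a subset of samples (group ids preserved)."""
        sub = {s: self.group_of[s] for s in sample_ids}
        reps = [r for r in self.representatives if r in sub]
        return Partition(sub, self.threshold, reps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.group_of), "group": list(self.group_of.values())}
        )


def _cluster(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage connected components under d <= threshold."""
    adj = csr_matrix(dm.values <= threshold)
    _, labels = connected_components(adj, directed=False)
    # renumber groups in order of first appearance for determinism
    remap: dict[int, int] = {}
    group_of: dict[str, int] = {}
    for sid, lab in zip(dm.ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        group_of[sid] = remap[lab]
    part = Partition(group_of, threshold)
    # representative = lexicographically smallest sample id in each group
    part.representatives = [
        min(part.members(g)) for g in range(part.n_groups)
    ]
    return part


def assign_mlgs(dm: DistanceMatrix) -> Partition:
    """Group samples into multilocus genotypes: components under d = 0.

    Every pair of individuals at non-zero genetic distance is treated as a
    separate MLG.  One representative per MLG (smallest sample id) is
    recorded for downstream ordination on unique genotypes.
    """
    return _cluster(dm, 0.0)


def assign_clonal_lineages(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage clone grouping under d <= threshold.

    ``threshold=0`` reduces exactly to :func:`assign_mlgs`.  Lineages coarsen
    monotonically as the threshold grows.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return _cluster(dm, threshold)


@dataclass
class DistanceHistogram:
    """Binned pairwise-distance counts plus the detected valley threshold."""

    bin_edges: np.ndarray
    counts: np.ndarray
    detected_threshold: float | None
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _valley_index(counts: np.ndarray, ratio: float = 0.5) -> int | None:
    """Index of the minimum-count bin between the first peak and the next one.

    The first peak is the first local maximum scanning from zero (the
    clone-mate peak); the second is the next local maximum beyond it whose
    intervening minimum drops below ``ratio`` times the smaller flanking
    peak — the prominence requirement keeps sampling noise *within* a mode
    from being mistaken for a valley.  Returns None when the distribution is
    effectively unimodal.
    """
    n = len(counts)

    def is_local_max(i: int) -> bool:
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n - 1 else -1
        return counts[i] > 0 and counts[i] >= left and counts[i] >= right

    first = next((i for i in range(n) if is_local_max(i)), None)
    if first is None:
        return None
    for j in range(first + 2, n):
        if is_local_max(j):
            between = counts[first + 1 : j]
            if between.size and between.min() <= ratio * min(counts[first], counts[j]):
                # first occurrence of the minimum within the valley
                return first + 1 + int(np.argmin(between))
    return None


def histogram_and_threshold(
    dm_or_values,
    bin_width: float = 0.01,
    *,
    include_self: bool = True,
    smooth_window: int = 0,
    valley_ratio: float = 0.5,
) -> DistanceHistogram:
    """Histogram of pairwise distances with automatic valley-threshold detection.

    Accepts a :class:`DistanceMatrix` (all ordered pairs are tallied,
    including self-comparisons, so n individuals yield n**2 comparisons —
    matching the bookkeeping convention of clonal-diversity histograms) or a
    raw 1-D array of distances.

    ``smooth_window`` > 1 applies a moving-average smoothing to the counts
    before valley search only; reported counts stay raw.  When no valley is
    found the threshold is ``None`` and a warning is emitted: the caller must
    supply a manual threshold.
    """
    if isinstance(dm_or_values, DistanceMatrix):
        vals = dm_or_values.values
        if include_self:
            data = vals.ravel()
        else:
            iu = np.triu_indices(len(dm_or_values), k=1)
            data = vals[iu]
    else:
        data = np.asarray(dm_or_values, dtype=float).ravel()
    if data.size < 1:
        raise ValueError("no distances to histogram")
    n_bins = max(1, int(np.ceil((max(data.max(), bin_width)) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < data.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(data, bins=edges)
    search = counts.astype(float)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        search = np.convolve(search, kernel, mode="same")
    vi = _valley_index(search, valley_ratio)
    if vi is None:
        warnings.warn(
            "pairwise-distance distribution appears unimodal; no clone "
            "threshold detected — supply one manually",
            stacklevel=2,
        )
        thr = None
    else:
        thr = float((edges[vi] + edges[vi + 1]) / 2.0)
    return DistanceHistogram(edges, counts, thr, int(data.size))


def simpson_complement(sizes, *, unbiased: bool = True) -> float:
    """Genotypic diversity 1 - lambda from MLG group sizes.

    With the unbiased estimator (default), lambda = sum n_i(n_i-1) / (N(N-1)):
    the probability that two individuals drawn *without* replacement share an
    MLG.  The biased plug-in sum((n_i/N)**2) is available for cross-checks.
    Returns 0 for a single group, 1 when every individual is its own MLG.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size and (sizes <= 0).any():
        raise ValueError("group sizes must be positive")
    n = sizes.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if unbiased:
        lam = float((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    else:
        lam = float(((sizes / n) ** 2).sum())
    return 1.0 - lam


def allele_richness(gs: GenotypeSet, taxon: str | None = None,
                    loci: list[str] | None = None) -> int:
    """Total count of distinct alleles over the panel (optionally one taxon)."""
    if taxon is not None:
        gs = gs.subset_taxa([taxon])
    if loci is None:
        loci = gs.locus_names
    total = 0
    for l in loci:
        seen: set[int] = set()
        for g in gs.genotypes:
            seen |= g.alleles.get(l, frozenset())
        total += len(seen)
    return total


def rarefied_richness(
    gs: GenotypeSet,
    taxon: str,
    n: int,
    *,
    reps: int = 1000,
    seed: int,
    loci: list[str] | None = None,
) -> float:
    """Mean distinct-allele count over random subsamples of size ``n``.

    Subsampling is without replacement, repeated ``reps`` times with a
    mandatory seed; equalises sample sizes so allelic richness can be
    compared across taxa fairly.
    """
    sub = gs.subset_taxa([taxon])
    ids = sub.sample_ids
    if n > len(ids):
        raise ValueError(f"subsample size {n} exceeds taxon sample count {len(ids)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(reps):
        chosen = rng.choice(len(ids), size=n, replace=False)
        total += allele_richness(sub.subset_samples([ids[i] for i in chosen]), loci=loci)
    return total / reps


def diversity_table(
    gs: GenotypeSet,
    mlg_partition: Partition,
    clone_partition: Partition | None = None,
    *,
    loci: list[str] | None = None,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Per-taxon diversity summary: N, A, Ng, 1 - lambda, Nc.

    ``mlg_partition`` (and optionally ``clone_partition``) must have been
    computed on the same samples; taxa whose samples are absent from the
    partitions are skipped with a warning.  ``loci`` restricts the
    allele-richness column to a panel subset.
    """
    rows = []
    for taxon in gs.taxa():
        sub = gs.subset_taxa([taxon])
        ids = sub.sample_ids
        if any(s not in mlg_partition.group_of for s in ids):
            warnings.warn(f"taxon {taxon!r} absent from partition; skipped", stacklevel=2)
            continue
        mlg_sizes = mlg_partition.restrict(ids).sizes()
        n = len(ids)
        row = {
            "taxon": taxon,
            "N": n,
            "A": allele_richness(gs, taxon, loci=loci),
            "Ng": len(mlg_sizes),
            "simpson_complement": (
                simpson_complement(mlg_sizes, unbiased=unbiased) if n >= 2 else np.nan
            ),
        }
        if clone_partition is not None and all(
            s in clone_partition.group_of for s in ids
        ):
            row["Nc"] = clone_partition.restrict(ids).n_groups
        rows.append(row)
    return pd.DataFrame(rows)
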