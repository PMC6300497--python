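"""Data model and delimited-text I/O for multilocus microsatellite genotypes.

The central container is :class:`GenotypeSet`: a marker panel (:class:`LocusDef`
per locus) plus one :class:`Genotype` per sampled individual.  Allele calls are
stored internally in *repeat units* (number of motif repeats), not fragment
sizes in base pairs, because the stepwise-mutation distance downstream is
defined on repeat counts.  An observed allele set is a set of *distinct*
alleles: microsatellite peak profiles in polyploids do not resolve copy
number, so dosage is deliberately not represented.

Input tables are simple CSVs with a declared header::

    sample_id,taxon,site,ploidy,LOCUS1,LOCUS2,...

where each locus cell holds 1..ploidy allele calls separated by ``/`` (e.g.
``150/154``) and missing data is a configurable sentinel (default ``0`` or
blank).  A GenAlEx-style one-column-per-allele layout can be converted to this
dialect trivially; the parser itself stays single-dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocusDef",
    "Genotype",
    "GenotypeSet",
    "DistanceMatrix",
    "GenotypeValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "read_locus_panel",
    "write_locus_panel",
    "read_distance_matrix",
    "write_distance_matrix",
]

GENOME_TAGS = ("none", "genomeA", "genomeB")


class GenotypeValidationError(ValueError):
    """Raised when a genotype table violates its declared constraints."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name : str
        Locus identifier, unique within a panel.
    repeat_len : int
        Length of the repeat motif in bp (>= 1); used to convert fragment
        sizes to repeat counts.
    genome_tag : str
        ``"none"`` for ordinary loci, or ``"genomeA"`` / ``"genomeB"`` for
        genome-specific loci that amplify only from one ancestral genome
        (used to count parental genome contributions in hybrids).
    offset : int
        Constant flanking length in bp subtracted before dividing by
        ``repeat_len`` when converting bp to repeat units.
    """

    name: str
    repeat_len: int = 2
    genome_tag: str = "none"
    offset: int = 0

    def __post_init__(self) -> None:
        if self.repeat_len < 1:
            raise ValueError(f"repeat_len must be >= 1, got {self.repeat_len}")
        if self.genome_tag not in GENOME_TAGS:
            raise ValueError(f"genome_tag must be one of {GENOME_TAGS}")

    def bp_to_repeats(self, bp: int) -> int:
        """Convert a fragment size in bp to a repeat count (integer division)."""
        r = (int(bp) - self.offset) // self.repeat_len
        if r <= 0:
            raise GenotypeValidationError(
                f"fragment size {bp} at locus {self.name} converts to "
                f"non-positive repeat count {r}"
            )
        return r

    def repeats_to_bp(self, repeats: int) -> int:
        return int(repeats) * self.repeat_len + self.offset


@dataclass
class Genotype:
    """One individual's allele profile across the panel.

    ``alleles`` maps locus name -> frozenset of distinct allele values in
    repeat units.  An empty set means the locus is missing (failed to
    amplify).  ``ploidy`` is ``None`` when unknown.
    """

    sample_id: str
    taxon: str = ""
    site: str = ""
    ploidy: int | None = None
    alleles: dict[str, frozenset[int]] = field(default_factory=dict)

    def validate(self, panel_names: set[str] | None = None) -> None:
        if self.ploidy is not None and self.ploidy not in (2, 3, 4):
            raise GenotypeValidationError(
                f"sample {self.sample_id}: ploidy must be 2, 3 or 4 (or unknown), "
                f"got {self.ploidy}"
            )
        for locus, obs in self.alleles.items():
            if panel_names is not None and locus not in panel_names:
                raise GenotypeValidationError(
                    f"sample {self.sample_id}: unknown locus {locus!r}"
                )
            if any(a <= 0 for a in obs):
                raise GenotypeValidationError(
                    f"sample {self.sample_id}, locus {locus}: non-positive allele"
                )
            if self.ploidy is not None and len(obs) > self.ploidy:
                raise GenotypeValidationError(
                    f"sample {self.sample_id}, locus {locus}: {len(obs)} distinct "
                    f"alleles exceed declared ploidy {self.ploidy}"
                )

    def scored_loci(self) -> set[str]:
        """Loci with at least one observed allele."""
        return {loc for loc, obs in self.alleles.items() if obs}

    def mlg_key(self, loci: list[str] | None = None) -> tuple:
        """Hashable multilocus-genotype key over ``loci`` (default: all scored)."""
        names = sorted(self.alleles) if loci is None else list(loci)
        return tuple(tuple(sorted(self.alleles.get(n, frozenset()))) for n in names)


@dataclass
class GenotypeSet:
    """A marker panel plus the genotypes scored on it."""

    panel: list[LocusDef]
    genotypes: list[Genotype]

    def __post_init__(self) -> None:
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise GenotypeValidationError("duplicate locus names in panel")
        pset = set(names)
        for g in self.genotypes:
            g.validate(pset)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    @property
    def sample_ids(self) -> list[str]:
        return [g.sample_id for g in self.genotypes]

    def locus(self, name: str) -> LocusDef:
        for l in self.panel:
            if l.name == name:
                return l
        raise KeyError(name)

    def by_id(self, sample_id: str) -> Genotype:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        raise KeyError(sample_id)

    def taxa(self) -> list[str]:
        out: list[str] = []
        for g in self.genotypes:
            if g.taxon not in out:
                out.append(g.taxon)
        return out

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeSet":
        wanted = set(sample_ids)
        return GenotypeSet(self.panel, [g for g in self.genotypes if g.sample_id in wanted])

    def subset_taxa(self, taxa: list[str]) -> "GenotypeSet":
        wanted = set(taxa)
        return GenotypeSet(self.panel, [g for g in self.genotypes if g.taxon in wanted])

    def subset_loci(self, loci: list[str]) -> "GenotypeSet":
        wanted = [l for l in self.panel if l.name in set(loci)]
        missing = set(loci) - {l.name for l in wanted}
        if missing:
            raise KeyError(f"loci not in panel: {sorted(missing)}")
        gts = [
            Genotype(
                g.sample_id,
                g.taxon,
                g.site,
                g.ploidy,
                {l.name: g.alleles.get(l.name, frozenset()) for l in wanted},
            )
            for g in self.genotypes
        ]
        return GenotypeSet(wanted, gts)


class DistanceMatrix:
    """Symmetric pairwise distance matrix with values in [0, 1], zero diagonal."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if len(set(ids)) != n:
            raise ValueError("duplicate ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("distance values outside [0, 1]")
        self.ids = list(ids)
        self.values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy 'condensed' order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# CSV I/O

_META_COLS = ("sample_id", "taxon", "site", "ploidy")


def read_genotype_table(
    path,
    panel: list[LocusDef],
    *,
    units: str = "bp",
    missing: tuple[str, ...] = ("0", ""),
    allele_sep: str = "/",
) -> GenotypeSet:
    """Read a CSV genotype table against a locus panel.

    ``units="bp"`` converts fragment sizes via each locus's ``repeat_len`` and
    ``offset``; ``units="repeats"`` takes the values as repeat counts directly.
    """
    if units not in ("bp", "repeats"):
        raise ValueError("units must be 'bp' or 'repeats'")
    by_name = {l.name: l for l in panel}
    genotypes: list[Genotype] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise GenotypeValidationError("empty genotype table")
        for col in _META_COLS:
            if col not in reader.fieldnames:
                raise GenotypeValidationError(f"missing required column {col!r}")
        locus_cols = [c for c in reader.fieldnames if c not in _META_COLS]
        unknown = [c for c in locus_cols if c not in by_name]
        if unknown:
            raise GenotypeValidationError(f"unknown loci in table header: {unknown}")
        for row in reader:
            ploidy_raw = (row["ploidy"] or "").strip()
            ploidy = int(ploidy_raw) if ploidy_raw and ploidy_raw.lower() != "na" else None
            alleles: dict[str, frozenset[int]] = {}
            for col in locus_cols:
                cell = (row[col] or "").strip()
                if cell in missing:
                    alleles[col] = frozenset()
                    continue
                calls = [c.strip() for c in cell.split(allele_sep) if c.strip()]
                calls = [c for c in calls if c not in missing]
                if not calls:
                    alleles[col] = frozenset()
                    continue
                locus = by_name[col]
                if units == "bp":
                    vals = frozenset(locus.bp_to_repeats(int(c)) for c in calls)
                else:
                    vals = frozenset(int(c) for c in calls)
                alleles[col] = vals
            g = Genotype(
                sample_id=row["sample_id"].strip(),
                taxon=row["taxon"].strip(),
                site=row["site"].strip(),
                ploidy=ploidy,
                alleles=alleles,
            )
            g.validate(set(by_name))
            genotypes.append(g)
    return GenotypeSet(panel, genotypes)


def write_genotype_table(gs: GenotypeSet, path, *, units: str = "repeats",
                         missing: str = "0", allele_sep: str = "/") -> None:
    """Write a GenotypeSet back to the CSV dialect ``read_genotype_table`` reads."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_META_COLS) + gs.locus_names)
        for g in gs.genotypes:
            row = [g.sample_id, g.taxon, g.site, "" if g.ploidy is None else g.ploidy]
            for locus in gs.panel:
                obs = sorted(g.alleles.get(locus.name, frozenset()))
                if not obs:
                    row.append(missing)
                elif units == "bp":
                    row.append(allele_sep.join(str(locus.repeats_to_bp(a)) for a in obs))
                else:
                    row.append(allele_sep.join(str(a) for a in obs))
            w.writerow(row)


def read_locus_panel(path) -> list[LocusDef]:
    """Read a locus panel CSV: name,repeat_len,genome_tag,offset."""
    panel = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            panel.append(
                LocusDef(
                    name=row["name"].strip(),
                    repeat_len=int(row.get("repeat_len", 2) or 2),
                    genome_tag=(row.get("genome_tag") or "none").strip() or "none",
                    offset=int(row.get("offset", 0) or 0),
                )
            )
    return panel


def write_locus_panel(panel: list[LocusDef], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "repeat_len", "genome_tag", "offset"])
        for l in panel:
            w.writerow([l.name, l.repeat_len, l.genome_tag, l.offset])


def write_distance_matrix(dm: DistanceMatrix, path, *, decimals: int = 9) -> None:
    """Write a square CSV distance matrix with an id header row/column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + dm.ids)
        for sid, row in zip(dm.ids, dm.values):
            w.writerow([sid] + [format(v, f".{decimals}f") for v in row])


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square CSV distance matrix; validates symmetry, range, diagonal."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError("empty distance matrix file")
    ids = rows[0][1:]
    vals = np.array([[float(x) for x in r[1:]] for r in rows[1:]], dtype=float)
    row_ids = [r[0] for r in rows[1:]]
    if row_ids != ids:
        raise ValueError("row ids do not match column ids")
    return DistanceMatrix(ids, vals)  # constructor validates
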