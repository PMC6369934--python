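"""Domain types and I/O for pooled-sequencing SNP nucleotide-count matrices.

The universal substrate of the package is the :class:`SNPMatrix`: per-SNP,
per-population biallelic read counts with genome coordinates and RAD-locus
identifiers.  Populations are pools of diploid individuals labelled by
habitat (``basic``, ``acidic`` or ``marine``); allele frequencies are always
estimated as read-count fractions within a pool.

Coordinates are 1-based inclusive internally; BED exports are 0-based
half-open.  A population with zero read depth at a SNP has an *undefined*
frequency, which propagates as NaN ("missing"), never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("poolscan")

HABITATS = ("basic", "acidic", "marine")
NUCLEOTIDES = ("A", "C", "G", "T")

#: sync-format nucleotide column order (popoolation2): A:T:C:G:N:del
_SYNC_ORDER = ("A", "T", "C", "G", "N", "del")

#: fraction of total depth above which a third allele invalidates a sync site
TRIALLELIC_TOLERANCE = 0.10


class ConfigError(ValueError):
    """Invalid configuration (unknown population, bad threshold, ...)."""


class ParseError(ValueError):
    """Malformed input file; carries the offending line number in the message."""


# ---------------------------------------------------------------------------
# population metadata and genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One pooled population sample.

    Parameters
    ----------
    name : str
        Short unique identifier (e.g. lake name).
    habitat : str
        One of ``basic``, ``acidic``, ``marine``.
    pool_size : int
        Number of diploid individuals in the pool (>= 1).
    group_tag : str, optional
        Free-form sub-sample label (e.g. marine sub-sample OBSM/ARDH).
    """

    name: str
    habitat: str
    pool_size: int
    group_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("population name must be non-empty")
        if self.habitat not in HABITATS:
            raise ConfigError(
                f"habitat {self.habitat!r} not in {HABITATS}")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate chromosome names in layout")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ConfigError("chromosome lengths must be > 0")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise ConfigError(f"unknown chromosome {chrom!r}")

    def order(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise ConfigError(f"unknown chromosome {chrom!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column TSV (name, length); '#' comments permitted."""
        chroms = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length") from exc
        return cls(tuple(chroms))

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.chromosomes))


def read_population_specs(path: str | Path) -> list[PopulationSpec]:
    """Read population metadata from a YAML (or JSON) list of mappings."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ParseError(f"{path}: expected a list of population mappings")
    return [PopulationSpec(**entry) for entry in raw]


def write_population_specs(pops: Sequence[PopulationSpec], path: str | Path) -> None:
    entries = []
    for p in pops:
        entry = {"name": p.name, "habitat": p.habitat, "pool_size": p.pool_size}
        if p.group_tag is not None:
            entry["group_tag"] = p.group_tag
        entries.append(entry)
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SNPMatrix:
    """Biallelic SNP read counts for a set of pooled populations.

    Records are kept sorted by (layout chromosome order, position) with no
    duplicate sites; every record carries one (ref_count, alt_count) pair per
    population.
    """

    populations: list[PopulationSpec]
    layout: GenomeLayout
    chrom: np.ndarray          # (n,) object
    pos: np.ndarray            # (n,) int64, 1-based
    locus_id: np.ndarray       # (n,) object
    ref: np.ndarray            # (n,) object, single nucleotide
    alt: np.ndarray            # (n,) object
    ref_counts: np.ndarray     # (n, k) int64
    alt_counts: np.ndarray     # (n, k) int64

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("population names must be unique")
        n, k = len(self.pos), len(self.populations)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.locus_id = np.asarray(self.locus_id, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64).reshape(n, k)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64).reshape(n, k)
        for arr, label in ((self.chrom, "chrom"), (self.locus_id, "locus_id"),
                           (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n:
                raise ConfigError(f"{label} length mismatch")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ConfigError("negative read counts")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ConfigError("ref and alt allele must differ")
        chrom_order = np.array([self.layout.order(c) for c in self.chrom])
        for c in set(self.chrom.tolist()):
            bad = self.pos[self.chrom == c] > self.layout.length(c)
            if bad.any():
                raise ConfigError(f"position beyond chromosome {c} length")
        order = np.lexsort((self.pos, chrom_order))
        if not np.array_equal(order, np.arange(n)):
            for name in ("chrom", "pos", "locus_id", "ref", "alt",
                         "ref_counts", "alt_counts"):
                setattr(self, name, getattr(self, name)[order])
        key = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(key)) != n:
            raise ConfigError("duplicate (chrom, pos) records")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def pop_index(self, name: str) -> int:
        try:
            return self.pop_names.index(name)
        except ValueError:
            raise ConfigError(f"unknown population {name!r}") from None

    def pops_by_habitat(self, habitat: str) -> list[str]:
        return [p.name for p in self.populations if p.habitat == habitat]

    def depths(self) -> np.ndarray:
        """(n, k) total read depth per SNP and population."""
        return self.ref_counts + self.alt_counts

    def freqs(self) -> np.ndarray:
        """(n, k) reference-allele frequency; NaN where depth is 0."""
        depth = self.depths().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, self.ref_counts / depth, np.nan)
        return f

    def pooled_freq(self, names: Sequence[str]) -> np.ndarray:
        """(n,) ref-allele frequency pooled (count-summed) over populations."""
        idx = [self.pop_index(nm) for nm in names]
        if not idx:
            raise ConfigError("empty population scope")
        r = self.ref_counts[:, idx].sum(axis=1).astype(float)
        d = r + self.alt_counts[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, r / d, np.nan)

    def maf(self, names: Sequence[str]) -> np.ndarray:
        """(n,) minor-allele frequency over the pooled scope; NaN if no depth."""
        f = self.pooled_freq(names)
        return np.minimum(f, 1.0 - f)

    def subset(self, mask: np.ndarray) -> "SNPMatrix":
        mask = np.asarray(mask)
        return SNPMatrix(
            populations=list(self.populations), layout=self.layout,
            chrom=self.chrom[mask], pos=self.pos[mask],
            locus_id=self.locus_id[mask], ref=self.ref[mask], alt=self.alt[mask],
            ref_counts=self.ref_counts[mask], alt_counts=self.alt_counts[mask])

    def site_lookup(self) -> dict[tuple[str, int], int]:
        return {(c, int(p)): i
                for i, (c, p) in enumerate(zip(self.chrom, self.pos))}

    def to_dataframe(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos, "locus_id": self.locus_id,
                "ref": self.ref, "alt": self.alt}
        for j, name in enumerate(self.pop_names):
            data[f"{name}:ref"] = self.ref_counts[:, j]
            data[f"{name}:alt"] = self.alt_counts[:, j]
        return pd.DataFrame(data)


def equal_matrices(a: SNPMatrix, b: SNPMatrix) -> bool:
    """Field-for-field equality of two SNP matrices (used in round-trip tests)."""
    return (a.populations == b.populations
            and a.layout == b.layout
            and np.array_equal(a.chrom, b.chrom)
            and np.array_equal(a.pos, b.pos)
            and np.array_equal(a.locus_id, b.locus_id)
            and np.array_equal(a.ref, b.ref)
            and np.array_equal(a.alt, b.alt)
            and np.array_equal(a.ref_counts, b.ref_counts)
            and np.array_equal(a.alt_counts, b.alt_counts))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_snp_matrix(matrix: SNPMatrix, path: str | Path,
                     fmt: str = "tsv") -> None:
    """Write a SNP matrix as TSV (native dialect) or popoolation2 sync."""
    if fmt == "tsv":
        _write_tsv(matrix, path)
    elif fmt == "sync":
        _write_sync(matrix, path)
    else:
        raise ConfigError(f"unknown format {fmt!r}")


def read_snp_matrix(path: str | Path, fmt: str,
                    populations: Sequence[PopulationSpec],
                    layout: GenomeLayout) -> SNPMatrix:
    """Read a SNP matrix from TSV or sync format.

    For sync input, per-population A:T:C:G:N:del counts are reduced to the
    two most frequent nucleotides overall (the sync reference base keeps the
    ``ref`` role when it is one of them); sites where a third allele exceeds
    10% of total depth are skipped with a logged warning.
    """
    if fmt == "tsv":
        return _read_tsv(path, populations, layout)
    if fmt == "sync":
        return _read_sync(path, populations, layout)
    raise ConfigError(f"unknown format {fmt!r}")


def _write_tsv(matrix: SNPMatrix, path: str | Path) -> None:
    cols = ["chrom", "pos", "locus_id", "ref", "alt"]
    cols += [f"{n}:{a}" for n in matrix.pop_names for a in ("ref", "alt")]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(matrix.n_snps):
            row = [matrix.chrom[i], str(matrix.pos[i]), matrix.locus_id[i],
                   matrix.ref[i], matrix.alt[i]]
            for j in range(matrix.n_pops):
                row += [str(matrix.ref_counts[i, j]), str(matrix.alt_counts[i, j])]
            fh.write("\t".join(row) + "\n")


def _read_tsv(path: str | Path, populations: Sequence[PopulationSpec],
              layout: GenomeLayout) -> SNPMatrix:
    lines = Path(path).read_text().splitlines()
    body = [(no, ln) for no, ln in enumerate(lines, 1)
            if ln.strip() and not ln.startswith("#")]
    if not body:
        raise ParseError(f"{path}: empty file")
    header = body[0][1].split("\t")
    expected = ["chrom", "pos", "locus_id", "ref", "alt"]
    expected += [f"{p.name}:{a}" for p in populations for a in ("ref", "alt")]
    if header != expected:
        raise ConfigError(
            f"{path}: header does not match the configured populations")
    k = len(populations)
    chrom, pos, locus, ref, alt, rc, ac = [], [], [], [], [], [], []
    for lineno, line in body[1:]:
        parts = line.split("\t")
        if len(parts) != 5 + 2 * k:
            raise ParseError(f"{path}:{lineno}: expected {5 + 2 * k} columns")
        try:
            pos.append(int(parts[1]))
            counts = [int(x) for x in parts[5:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer field") from exc
        chrom.append(parts[0])
        locus.append(parts[2])
        ref.append(parts[3])
        alt.append(parts[4])
        rc.append(counts[0::2])
        ac.append(counts[1::2])
    return SNPMatrix(list(populations), layout,
                     np.array(chrom, dtype=object), np.array(pos),
                     np.array(locus, dtype=object),
                     np.array(ref, dtype=object), np.array(alt, dtype=object),
                     np.array(rc), np.array(ac))


def _write_sync(matrix: SNPMatrix, path: str | Path) -> None:
    ref_slot = [_SYNC_ORDER.index(b) for b in matrix.ref]
    alt_slot = [_SYNC_ORDER.index(b) for b in matrix.alt]
    with open(path, "w") as fh:
        for i in range(matrix.n_snps):
            row = [matrix.chrom[i], str(matrix.pos[i]), matrix.ref[i]]
            for j in range(matrix.n_pops):
                counts = [0] * 6
                counts[ref_slot[i]] = int(matrix.ref_counts[i, j])
                counts[alt_slot[i]] = int(matrix.alt_counts[i, j])
                row.append(":".join(str(c) for c in counts))
            fh.write("\t".join(row) + "\n")


def _read_sync(path: str | Path, populations: Sequence[PopulationSpec],
               layout: GenomeLayout) -> SNPMatrix:
    k = len(populations)
    chrom, pos, locus, ref, alt, rc, ac = [], [], [], [], [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3 + k:
            raise ConfigError(
                f"{path}:{lineno}: expected {3 + k} columns for "
                f"{k} populations, found {len(parts)}")
        try:
            p = int(parts[1])
            per_pop = []
            for cell in parts[3:]:
                vals = [int(x) for x in cell.split(":")]
                if len(vals) != 6:
                    raise ValueError
                per_pop.append(vals)
            per_pop_arr = np.array(per_pop)  # (k, 6)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed sync counts") from exc
        totals = per_pop_arr[:, :4].sum(axis=0)  # per A,T,C,G
        refbase = parts[2]
        # two most frequent nucleotides overall; ties broken by A,T,C,G order
        rank = sorted(range(4), key=lambda s: (-totals[s], s))
        top2 = rank[:2]
        if refbase in NUCLEOTIDES and _SYNC_ORDER.index(refbase) in top2:
            ref_slot = _SYNC_ORDER.index(refbase)
            alt_slot = top2[0] if top2[0] != ref_slot else top2[1]
        else:
            ref_slot, alt_slot = top2
        third = per_pop_arr.sum() - totals[ref_slot] - totals[alt_slot]
        total_depth = per_pop_arr.sum()
        if total_depth > 0 and third > TRIALLELIC_TOLERANCE * total_depth:
            logger.warning("%s:%d: skipping site with >%.0f%% third-allele reads",
                           path, lineno, TRIALLELIC_TOLERANCE * 100)
            continue
        chrom.append(parts[0])
        pos.append(p)
        locus.append(f"{parts[0]}:{p}")
        ref.append(_SYNC_ORDER[ref_slot])
        alt.append(_SYNC_ORDER[alt_slot])
        rc.append(per_pop_arr[:, ref_slot].tolist())
        ac.append(per_pop_arr[:, alt_slot].tolist())
    return SNPMatrix(list(populations), layout,
                     np.array(chrom, dtype=object), np.array(pos),
                     np.array(locus, dtype=object),
                     np.array(ref, dtype=object), np.array(alt, dtype=object),
                     np.array(rc), np.array(ac))


# ---------------------------------------------------------------------------
# population arithmetic
# ---------------------------------------------------------------------------

def combine_populations(matrix: SNPMatrix, names: Sequence[str],
                        new_name: str) -> SNPMatrix:
    """Merge several population pools into one by summing read counts.

    The merged pool replaces the named populations (appended last); its
    pool_size is the sum of the members'.  Merging weights sub-samples by
    read depth, matching how the two marine sub-samples are combined into a
    single ancestor-proxy population.
    """
    if len(set(names)) != len(names) or len(names) < 2:
        raise ConfigError("need at least two distinct populations to combine")
    idx = [matrix.pop_index(n) for n in names]
    habitats = {matrix.populations[i].habitat for i in idx}
    if len(habitats) != 1:
        raise ConfigError("cannot combine populations from different habitats")
    if new_name in set(matrix.pop_names) - set(names):
        raise ConfigError(f"population {new_name!r} already exists")
    keep = [j for j in range(matrix.n_pops) if j not in idx]
    new_spec = PopulationSpec(
        name=new_name, habitat=habitats.pop(),
        pool_size=sum(matrix.populations[i].pool_size for i in idx))
    ref = np.concatenate(
        [matrix.ref_counts[:, keep],
         matrix.ref_counts[:, idx].sum(axis=1, keepdims=True)], axis=1)
    alt = np.concatenate(
        [matrix.alt_counts[:, keep],
         matrix.alt_counts[:, idx].sum(axis=1, keepdims=True)], axis=1)
    return SNPMatrix([matrix.populations[j] for j in keep] + [new_spec],
                     matrix.layout, matrix.chrom.copy(), matrix.pos.copy(),
                     matrix.locus_id.copy(), matrix.ref.copy(),
                     matrix.alt.copy(), ref, alt)
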