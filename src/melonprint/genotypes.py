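"""Genotype-matrix data model, I/O and per-locus / per-variety diversity statistics.

The central object is :class:`GenotypeMatrix`: a varieties x loci table of
unordered diploid allele pairs.  SSR alleles are non-negative integer repeat
numbers; SNP alleles are single bases.  A cell is either fully observed or
fully missing — missing cells are excluded from every statistic and are never
imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SSR = "SSR"
SNP = "SNP"
MISSING_TOKEN = "./."
_SNP_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class Marker:
    """One marker of a panel: an SSR tract or a SNP site."""

    marker_id: str
    type: str  # SSR or SNP
    chrom: str = "."
    pos: int = 0  # 1-based
    motif: str | None = None  # SSR only
    ref: str | None = None  # SNP only

    def __post_init__(self):
        if self.type not in (SSR, SNP):
            raise ValueError(f"marker type must be SSR or SNP, got {self.type!r}")


class MarkerPanel:
    """Ordered collection of markers with unique ids.

    Positions are 1-based; within a chromosome markers are expected in
    ascending position order (enforced at construction).
    """

    def __init__(self, markers: Sequence[Marker]):
        ids = [m.marker_id for m in markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker ids: {dup}")
        by_chrom: dict[str, int] = {}
        for m in markers:
            prev = by_chrom.get(m.chrom)
            if prev is not None and m.pos and prev and m.pos < prev:
                raise ValueError(
                    f"markers out of position order on {m.chrom} at {m.marker_id}"
                )
            by_chrom[m.chrom] = m.pos
        self.markers: list[Marker] = list(markers)
        self._index = {m.marker_id: i for i, m in enumerate(self.markers)}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, key) -> Marker:
        if isinstance(key, str):
            return self.markers[self._index[key]]
        return self.markers[key]

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def subset(self, marker_ids: Iterable[str]) -> "MarkerPanel":
        return MarkerPanel([self[i] for i in marker_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [m.marker_id for m in self.markers],
                "type": [m.type for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "motif": [m.motif or "" for m in self.markers],
                "ref": [m.ref or "" for m in self.markers],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        markers = [
            Marker(
                marker_id=str(r.marker_id),
                type=str(r.type),
                chrom=str(r.chrom),
                pos=int(r.pos),
                motif=(str(r.motif) or None) if str(r.type) == SSR else None,
                ref=(str(r.ref) or None) if str(r.type) == SNP else None,
            )
            for r in df.itertuples()
        ]
        return cls(markers)


def _parse_allele(token: str, marker: Marker):
    if marker.type == SSR:
        if not re.fullmatch(r"\d+", token):
            raise ValueError(
                f"bad SSR allele {token!r} at {marker.marker_id} (expect repeat number)"
            )
        return int(token)
    if token not in _SNP_ALLELES:
        raise ValueError(f"bad SNP allele {token!r} at {marker.marker_id}")
    return token


class GenotypeMatrix:
    """Varieties x markers table of unordered diploid genotypes.

    Cells are stored per locus as integer codes into that locus's sorted
    observed allele table (-1 = missing), which keeps pairwise operations
    vectorizable while round-tripping the original allele labels exactly.
    """

    def __init__(self, varieties: Sequence[str], panel: MarkerPanel, cells):
        """``cells[i][j]`` is an (a, b) allele tuple or None for missing."""
        varieties = list(varieties)
        if len(set(varieties)) != len(varieties):
            dup = sorted({v for v in varieties if varieties.count(v) > 1})
            raise ValueError(f"duplicate variety names: {dup}")
        n, m = len(varieties), len(panel)
        alleles: list[list] = [None] * m
        codes = np.full((n, m, 2), -1, dtype=np.int16)
        for j in range(m):
            observed = set()
            for i in range(n):
                cell = cells[i][j]
                if cell is not None:
                    observed.update(cell)
            table = sorted(observed)
            lookup = {a: c for c, a in enumerate(table)}
            alleles[j] = table
            for i in range(n):
                cell = cells[i][j]
                if cell is None:
                    continue
                a, b = sorted(lookup[x] for x in cell)
                codes[i, j, 0] = a
                codes[i, j, 1] = b
        self.varieties = varieties
        self.panel = panel
        self.allele_tables: list[list] = alleles
        self.codes = codes

    # -- basic geometry -------------------------------------------------
    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def cell(self, i: int, j: int):
        """Unordered allele pair at (variety i, locus j), or None if missing."""
        a, b = self.codes[i, j]
        if a < 0:
            return None
        table = self.allele_tables[j]
        return (table[a], table[b])

    def observed_mask(self) -> np.ndarray:
        """Boolean (n, m): True where the cell is observed."""
        return self.codes[:, :, 0] >= 0

    def genotype_ids(self) -> np.ndarray:
        """Int32 (n, m) array giving each cell a per-locus genotype id; -1 missing.

        Two cells at the same locus share an id iff their unordered allele
        pairs are equal.
        """
        a = self.codes[:, :, 0].astype(np.int32)
        b = self.codes[:, :, 1].astype(np.int32)
        k = np.array([max(len(t), 1) for t in self.allele_tables], dtype=np.int32)
        gid = a * k[None, :] + b
        gid[a < 0] = -1
        return gid

    def subset_loci(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.panel.index_of(m) for m in marker_ids]
        return self._subset(range(self.n_varieties), idx)

    def subset_varieties(self, names: Iterable[str]) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.varieties)}
        idx = [pos[v] for v in names]
        return self._subset(idx, range(self.n_loci))

    def subset_type(self, marker_type: str) -> "GenotypeMatrix":
        ids = [m.marker_id for m in self.panel if m.type == marker_type]
        return self.subset_loci(ids)

    def _subset(self, vi, li) -> "GenotypeMatrix":
        vi, li = list(vi), list(li)
        cells = [[self.cell(i, j) for j in li] for i in vi]
        return GenotypeMatrix(
            [self.varieties[i] for i in vi],
            MarkerPanel([self.panel[j] for j in li]),
            cells,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.varieties == other.varieties
            and self.panel.marker_ids == other.panel.marker_ids
            and all(
                self.cell(i, j) == other.cell(i, j)
                for i in range(self.n_varieties)
                for j in range(self.n_loci)
            )
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read a genotype CSV/TSV: header ``variety,<marker ids...>``, cells "a/b" or "./.".

    The file's marker columns must match the panel's ids (any order is
    rejected to avoid silent misalignment).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns[0] != "variety":
        raise ValueError("first column must be 'variety'")
    file_ids = list(df.columns[1:])
    if file_ids != panel.marker_ids:
        raise ValueError("genotype file marker columns do not match panel order")
    varieties = df["variety"].tolist()
    cells = []
    for _, row in df.iterrows():
        r = []
        for m in panel:
            token = row[m.marker_id].strip()
            if token == MISSING_TOKEN:
                r.append(None)
                continue
            parts = token.split("/")
            if len(parts) != 2:
                raise ValueError(f"bad genotype cell {token!r} at {m.marker_id}")
            r.append(tuple(_parse_allele(p, m) for p in parts))
        cells.append(r)
    return GenotypeMatrix(varieties, panel, cells)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write the genotype CSV/TSV dialect read by :func:`read_genotypes`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path, "w") as fh:
        fh.write(sep.join(["variety"] + matrix.panel.marker_ids) + "\n")
        for i, v in enumerate(matrix.varieties):
            row = [v]
            for j in range(matrix.n_loci):
                cell = matrix.cell(i, j)
                row.append(MISSING_TOKEN if cell is None else f"{cell[0]}/{cell[1]}")
            fh.write(sep.join(row) + "\n")


def read_genotypes_vcf(path, sample_names: Sequence[str] | None = None) -> GenotypeMatrix:
    """Build a SNP GenotypeMatrix from the GT fields of a (multi-sample) VCF."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(sample_names or vf.header.samples)
    markers: list[Marker] = []
    cols: list[list] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue  # SNPs only
        alleles = (rec.ref, rec.alts[0])
        mid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
        markers.append(Marker(mid, SNP, rec.chrom, rec.pos, ref=rec.ref))
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or None in gt:
                col.append(None)
            else:
                col.append(tuple(alleles[g] for g in gt))
        cols.append(col)
    cells = [[cols[j][i] for j in range(len(markers))] for i in range(len(samples))]
    return GenotypeMatrix(samples, MarkerPanel(markers), cells)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def fragment_size_to_repeats(size: float, offset: float, motif_len: int) -> int:
    """Convert an SSR fragment size (bp) to a repeat number.

    ``repeat = round((size - offset) / motif_len)`` with a per-locus offset
    (the non-repeat part of the amplicon).  Bruvo-type distances need repeat
    counts, not raw sizes.
    """
    if motif_len <= 0:
        raise ValueError("motif_len must be positive")
    r = round((size - offset) / motif_len)
    if r < 0:
        raise ValueError(f"size {size} below offset {offset}")
    return int(r)


def allele_frequencies(matrix: GenotypeMatrix, locus) -> dict:
    """Allele frequency vector at a locus over 2 x (non-missing varieties) draws."""
    j = locus if isinstance(locus, int) else matrix.panel.index_of(locus)
    codes = matrix.codes[:, j, :].ravel()
    codes = codes[codes >= 0]
    table = matrix.allele_tables[j]
    if codes.size == 0:
        return {}
    counts = np.bincount(codes, minlength=len(table))
    total = counts.sum()
    return {table[c]: counts[c] / total for c in range(len(table)) if counts[c] > 0}


def pic(p) -> float:
    """Polymorphism information content as gene diversity: ``1 - sum(p_i^2)``.

    Caps at 0.5 for a biallelic locus.  The classical Botstein PIC (which
    caps at 0.375 for biallelic loci) is available as :func:`pic_botstein`.
    """
    freqs = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    return float(1.0 - np.sum(freqs**2))


def pic_botstein(p) -> float:
    """Botstein et al. PIC: ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``."""
    freqs = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    sq = freqs**2
    cross = np.sum(np.outer(sq, sq)) - np.sum(sq**2)
    return float(1.0 - np.sum(sq) - cross)


def locus_heterozygosity(matrix: GenotypeMatrix, locus) -> float:
    """Observed fraction of heterozygous genotypes among non-missing cells."""
    j = locus if isinstance(locus, int) else matrix.panel.index_of(locus)
    a, b = matrix.codes[:, j, 0], matrix.codes[:, j, 1]
    obs = a >= 0
    if not obs.any():
        return float("nan")
    return float(np.mean(a[obs] != b[obs]))


def variety_heterozygosity(matrix: GenotypeMatrix, variety) -> float:
    """Observed fraction of heterozygous loci for one variety."""
    i = variety if isinstance(variety, int) else matrix.varieties.index(variety)
    a, b = matrix.codes[i, :, 0], matrix.codes[i, :, 1]
    obs = a >= 0
    if not obs.any():
        return float("nan")
    return float(np.mean(a[obs] != b[obs]))


def missing_rates(matrix: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """(per-locus, per-variety) missing-rate vectors."""
    miss = matrix.codes[:, :, 0] < 0
    per_locus = pd.Series(miss.mean(axis=0), index=matrix.panel.marker_ids)
    per_variety = pd.Series(miss.mean(axis=1), index=matrix.varieties)
    return per_locus, per_variety


@dataclass
class LocusStats:
    marker_id: str
    n_alleles: int
    frequencies: dict = field(repr=False)
    pic: float = 0.0
    he_obs: float = 0.0
    missing_rate: float = 0.0


def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary table: allele count, PIC, observed He, missing rate."""
    per_locus_missing, _ = missing_rates(matrix)
    rows = []
    for j, m in enumerate(matrix.panel):
        p = allele_frequencies(matrix, j)
        rows.append(
            {
                "marker_id": m.marker_id,
                "type": m.type,
                "n_alleles": len(p),
                "pic": pic(p) if p else float("nan"),
                "he_obs": locus_heterozygosity(matrix, j),
                "missing_rate": per_locus_missing.iloc[j],
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")


def qc_filter_loci(
    matrix: GenotypeMatrix, min_pic: float = 0.1, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop loci with PIC < min_pic or missing rate > max_missing.

    Returns the filtered matrix (locus order preserved) and the removed ids.
    """
    stats = locus_stats(matrix)
    bad = stats.index[
        (stats["pic"].fillna(0.0) < min_pic) | (stats["missing_rate"] > max_missing)
    ]
    removed = list(bad)
    keep = [m for m in matrix.panel.marker_ids if m not in set(removed)]
    return matrix.subset_loci(keep), removed
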