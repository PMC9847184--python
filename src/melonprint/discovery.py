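"""Genome-wide SSR scanning and "perfect" SSR/SNP marker filtering.

A perfect marker is one whose site (the SSR tract or the SNP base) and both
50-bp flanking sequences are free of any other variation and, for SNPs,
uniquely mappable — so that a short amplicon genotypes it robustly.

Coordinates are 1-based inclusive throughout this module.  Windows clipped at
contig edges fail the filters rather than shrink.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

_DNA = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the motif (same strand only)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SSRLocus:
    """A perfect microsatellite tract: ``n_repeats`` full copies of ``motif``."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str  # canonical (smallest rotation), primitive, length 2-6
    n_repeats: int

    @property
    def tract_len(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpCandidate:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    missing_rate: float
    het_rate: float
    maf: float
    n_alts: int = 1  # >1 marks a multi-allelic record


@dataclass
class PerfectFilterConfig:
    """Thresholds of the perfect-marker screen.

    flank_bp: clean-flank half-width in bp.
    major_allele_read_freq: minimum per-accession major SSR allele read
        frequency.
    max_missing / max_het / min_maf: SNP cohort thresholds.
    min_repeats: minimum full-motif copies per motif length (SSR mining
        parameter; common defaults 5 for dimers, 4 for trimers, 3 for 4-6-mers).
    max_tract_len: SSR tracts at or above this length are discarded.
    count_filtered_variants: whether VCF records with FILTER != PASS still
        count as variation in a flank.
    """

    flank_bp: int = 50
    major_allele_read_freq: float = 0.7
    max_missing: float = 0.1
    max_het: float = 0.1
    min_maf: float = 0.05
    min_repeats: dict[int, int] = field(
        default_factory=lambda: {2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    max_tract_len: int = 50
    count_filtered_variants: bool = True


# ---------------------------------------------------------------------------
# SSR scanning
# ---------------------------------------------------------------------------

def _period_runs(seq: str, k: int):
    """Maximal intervals [a, b) (0-based, half-open) where seq has period k.

    Only intervals of length >= 2k are yielded: a single motif copy is not a
    repeat.
    """
    n = len(seq)
    if n < 2 * k:
        return
    i = 0
    while i < n - k:
        if seq[i] == seq[i + k]:
            a = i
            while i < n - k and seq[i] == seq[i + k]:
                i += 1
            # interval of period k is [a, i + k)
            yield a, i + k
        else:
            i += 1


def scan_ssrs(genome: dict[str, str], config: PerfectFilterConfig | None = None) -> list[SSRLocus]:
    """Scan sequences for maximal perfect SSR tracts with 2-6-bp motifs.

    For every motif length k the maximal period-k intervals are located; an
    interval of length L yields a tract of ``floor(L/k)`` full copies anchored
    at its left end.  Tracts whose motif is periodic (a shorter-unit repeat in
    disguise), that contain N, that have fewer than the configured minimum
    copies, or whose length reaches ``max_tract_len`` are discarded.
    Remaining overlaps are resolved longest-first, then leftmost.
    """
    cfg = config or PerfectFilterConfig()
    out: list[SSRLocus] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in {chrom}: {sorted(bad)}")
        found: list[SSRLocus] = []
        for k in range(2, 7):
            min_rep = cfg.min_repeats.get(k, 3)
            for a, b in _period_runs(seq, k):
                motif = seq[a : a + k]
                if not is_primitive(motif):
                    continue
                n_rep = (b - a) // k
                if n_rep < min_rep:
                    continue
                tract_len = n_rep * k
                if tract_len >= cfg.max_tract_len:
                    continue
                tract = seq[a : a + tract_len]
                if "N" in tract:
                    continue
                found.append(
                    SSRLocus(chrom, a + 1, a + tract_len, canonical_motif(motif), n_rep)
                )
        # longest-first, then leftmost, greedy non-overlap resolution
        found.sort(key=lambda L: (-L.tract_len, L.start, L.motif))
        kept: list[SSRLocus] = []
        occupied: list[tuple[int, int]] = []
        for loc in found:
            if any(loc.start <= e and s <= loc.end for s, e in occupied):
                continue
            kept.append(loc)
            occupied.append((loc.start, loc.end))
        kept.sort(key=lambda L: L.start)
        out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# Variant catalog
# ---------------------------------------------------------------------------

class VariantCatalog:
    """Positions of SNPs/indels per chromosome, queryable by interval.

    Built from a VCF (``from_vcf``) or directly from (chrom, pos, is_indel)
    triples.  Indels occupy ``[pos, pos + len(ref) - 1]``.
    """

    def __init__(self, records: list[tuple[str, int, int]]):
        """records: (chrom, start, end) 1-based inclusive spans of variants."""
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        per: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in records:
            per.setdefault(chrom, []).append((s, e))
        for chrom, spans in per.items():
            spans.sort()
            self._by_chrom[chrom] = ([s for s, _ in spans], [e for _, e in spans])

    @classmethod
    def from_vcf(cls, path, include_filtered: bool = True) -> "VariantCatalog":
        import pysam

        recs = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if not include_filtered:
                    filt = list(rec.filter.keys())
                    if filt and filt != ["PASS"]:
                        continue
                span = max(
                    [len(rec.ref)] + [len(a) for a in (rec.alts or []) if a is not None]
                )
                recs.append((rec.chrom, rec.pos, rec.pos + len(rec.ref) - 1))
        return cls(recs)

    def in_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff any variant span intersects [start, end] (1-based incl.)."""
        got = self._by_chrom.get(chrom)
        if got is None:
            return False
        starts, ends = got
        # candidates whose start <= end; check their ends against start
        hi = bisect_right(starts, end)
        return any(e >= start for e in ends[:hi])

    def count_in_interval(
        self, chrom: str, start: int, end: int, exclude_site: int | None = None
    ) -> int:
        """Number of variant spans intersecting [start, end]; optionally skip
        the single-base span at ``exclude_site`` (a candidate's own record)."""
        got = self._by_chrom.get(chrom)
        if got is None:
            return 0
        starts, ends = got
        hi = bisect_right(starts, end)
        n = 0
        for s, e in zip(starts[:hi], ends[:hi]):
            if e < start:
                continue
            if exclude_site is not None and s == e == exclude_site:
                continue
            n += 1
        return n


# ---------------------------------------------------------------------------
# Perfect filters
# ---------------------------------------------------------------------------

def filter_perfect_ssr(
    locus: SSRLocus,
    variants: VariantCatalog,
    per_accession_major_allele_freq,
    config: PerfectFilterConfig | None = None,
    *,
    all_ssrs: list[SSRLocus] | None = None,
    contig_len: int | None = None,
) -> tuple[bool, list[str]]:
    """Apply the perfect-SSR screen to one tract.

    Passes iff the tract plus both ``flank_bp`` flanks contain no SNP/indel
    and no other SSR tract, and every accession's major-allele read frequency
    exceeds the threshold.  ``per_accession_major_allele_freq`` is a mapping
    (or pandas Series) accession -> frequency for this locus; a missing /NaN
    entry means the accession had no reads and fails the screen.
    """
    cfg = config or PerfectFilterConfig()
    reasons: list[str] = []
    lo = locus.start - cfg.flank_bp
    hi = locus.end + cfg.flank_bp
    if lo < 1 or (contig_len is not None and hi > contig_len):
        reasons.append("flank_off_contig")
    else:
        if variants.in_interval(locus.chrom, lo, hi):
            reasons.append("variant_in_flank")
        if all_ssrs is not None:
            for other in all_ssrs:
                if other is locus or other == locus:
                    continue
                if other.chrom == locus.chrom and other.start <= hi and other.end >= lo:
                    reasons.append("ssr_in_flank")
                    break
    freqs = dict(per_accession_major_allele_freq)
    if not freqs:
        reasons.append("no_coverage")
    else:
        import math

        for acc, f in freqs.items():
            if f is None or (isinstance(f, float) and math.isnan(f)):
                reasons.append("no_coverage")
                break
            if f <= cfg.major_allele_read_freq:
                reasons.append("low_major_freq")
                break
    return (not reasons), reasons


def flank_is_unique(genome: dict[str, str], chrom: str, pos: int, flank_bp: int = 50) -> bool:
    """True iff the +-flank_bp window around pos occurs exactly once genome-wide.

    The focal base is masked (matches any base); both strands are counted, so
    a reverse-complement copy elsewhere also defeats uniqueness.  A window
    extending past a contig end is not unique by definition here.
    """
    seq = genome.get(chrom)
    if seq is None:
        return False
    seq = seq.upper()
    lo = pos - flank_bp - 1  # 0-based
    hi = pos + flank_bp  # exclusive
    if lo < 0 or hi > len(seq):
        return False
    window = seq[lo:hi]
    pattern = re.escape(window[:flank_bp]) + "." + re.escape(window[flank_bp + 1 :])
    rx = re.compile("(?=" + pattern + ")")
    count = 0
    for s in genome.values():
        s = s.upper()
        count += sum(1 for _ in rx.finditer(s))
        count += sum(1 for _ in rx.finditer(reverse_complement(s)))
    # the site itself matches once on the forward strand; if the (masked)
    # window also matches its own reverse complement it is seen once more.
    self_hits = 1 + (1 if re.fullmatch(pattern, reverse_complement(window)) else 0)
    return count == self_hits


def filter_perfect_snp(
    c: SnpCandidate,
    variants: VariantCatalog,
    genome: dict[str, str],
    config: PerfectFilterConfig | None = None,
) -> tuple[bool, list[str]]:
    """Apply the perfect-SNP screen: cohort thresholds plus clean, unique flanks."""
    cfg = config or PerfectFilterConfig()
    reasons: list[str] = []
    if c.n_alts != 1:
        return False, ["multiallelic"]
    if not (c.missing_rate < cfg.max_missing):
        reasons.append("high_missing")
    if not (c.het_rate < cfg.max_het):
        reasons.append("high_het")
    if not (c.maf > cfg.min_maf):
        reasons.append("low_maf")
    # the candidate's own record is excluded; any other variant in the flank fails
    n_flank = variants.count_in_interval(
        c.chrom, c.pos - cfg.flank_bp, c.pos + cfg.flank_bp, exclude_site=c.pos
    )
    if n_flank > 0:
        reasons.append("variant_in_flank")
    if not flank_is_unique(genome, c.chrom, c.pos, cfg.flank_bp):
        reasons.append("flank_not_unique")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Cohort statistics from a VCF + panel output
# ---------------------------------------------------------------------------

def snp_candidates_from_vcf(path) -> list[SnpCandidate]:
    """Compute per-site missing/het/MAF across the VCF's samples."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        n_samples = len(vf.header.samples)
        for rec in vf:
            alts = [a for a in (rec.alts or []) if a is not None]
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                continue  # indel: not a SNP candidate
            n_miss = n_het = 0
            counts: dict[int, int] = {}
            for s in rec.samples.values():
                gt = s.get("GT")
                if gt is None or None in gt:
                    n_miss += 1
                    continue
                if gt[0] != gt[1]:
                    n_het += 1
                for g in gt:
                    counts[g] = counts.get(g, 0) + 1
            n_called = n_samples - n_miss
            total = sum(counts.values())
            if total and len(counts) >= 2:
                maf = sorted(counts.values())[-2] / total
            else:
                maf = 0.0
            out.append(
                SnpCandidate(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0] if alts else ".",
                    missing_rate=n_miss / n_samples if n_samples else 1.0,
                    het_rate=n_het / n_called if n_called else 0.0,
                    maf=maf,
                    n_alts=len(alts),
                )
            )
    return out


def write_panel_tsv(path, ssr_results, snp_results) -> None:
    """Write the discovery report: one row per candidate with pass/fail + reasons.

    ssr_results: iterable of (SSRLocus, passed, reasons);
    snp_results: iterable of (SnpCandidate, passed, reasons).
    """
    with open(path, "w") as fh:
        fh.write("marker_id\ttype\tchrom\tpos\tmotif\tref\tstatus\treasons\n")
        for i, (loc, ok, reasons) in enumerate(ssr_results, 1):
            fh.write(
                f"SSR{i:04d}\tSSR\t{loc.chrom}\t{loc.start}-{loc.end}\t{loc.motif}\t.\t"
                f"{'pass' if ok else 'fail'}\t{','.join(reasons) or '.'}\n"
            )
        for i, (c, ok, reasons) in enumerate(snp_results, 1):
            fh.write(
                f"SNP{i:04d}\tSNP\t{c.chrom}\t{c.pos}\t.\t{c.ref}\t"
                f"{'pass' if ok else 'fail'}\t{','.join(reasons) or '.'}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
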