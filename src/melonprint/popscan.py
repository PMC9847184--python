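"""SNP-index scans and subspecies-diagnostic marker evaluation.

The SNP-index of a population at a SNP is its reference-allele frequency
computed from genotype calls.  Sliding-window means of the index along each
chromosome, and the per-window absolute between-population difference
(delta SNP-index), localize regions of fixed divergence; individual loci
with delta = 1 are alternatively fixed and are candidate diagnostic markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import SNP, GenotypeMatrix, MarkerPanel


@dataclass
class PopFreqTable:
    """Per-locus x per-population reference-allele frequency and allele counts."""

    index: pd.DataFrame  # loci x populations, SNP-index (NaN if no calls)
    counts: pd.DataFrame  # loci x populations, observed allele draws
    panel: MarkerPanel


def snp_index(matrix: GenotypeMatrix, labels) -> PopFreqTable:
    """Reference-allele frequency per SNP locus and population.

    ``labels`` maps variety -> population (dict or aligned sequence); entries
    of None are excluded.  Only SNP loci with a declared reference allele are
    tabulated.
    """
    if isinstance(labels, dict):
        lab = [labels.get(v) for v in matrix.varieties]
    else:
        lab = list(labels)
    pops = sorted({l for l in lab if l is not None})
    snp_loci = [
        (j, mk) for j, mk in enumerate(matrix.panel) if mk.type == SNP and mk.ref
    ]
    idx_by_pop = {
        p: np.array([i for i, l in enumerate(lab) if l == p], dtype=int) for p in pops
    }
    ids = [mk.marker_id for _, mk in snp_loci]
    freq = pd.DataFrame(np.nan, index=ids, columns=pops)
    cnt = pd.DataFrame(0, index=ids, columns=pops)
    for j, mk in snp_loci:
        table = matrix.allele_tables[j]
        try:
            ref_code = table.index(mk.ref)
        except ValueError:
            ref_code = None  # reference allele never observed
        for p in pops:
            codes = matrix.codes[idx_by_pop[p], j, :]
            obs = codes[:, 0] >= 0
            alleles = codes[obs].ravel()
            n = alleles.size
            cnt.loc[mk.marker_id, p] = n
            if n:
                n_ref = int(np.sum(alleles == ref_code)) if ref_code is not None else 0
                freq.loc[mk.marker_id, p] = n_ref / n
    panel = MarkerPanel([mk for _, mk in snp_loci])
    return PopFreqTable(freq, cnt, panel)


def window_track(
    pft: PopFreqTable,
    pop_a: str,
    pop_b: str,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window mean SNP-index per population and delta SNP-index.

    Windows are half-open [start, start + window), start at position 1 and
    advance by ``step``; the last window is truncated at the chromosome end
    (taken from ``chrom_lengths`` or the last SNP position).  A window with no
    SNPs carries NaN, not 0.  Window means are unweighted over the SNPs they
    contain.
    """
    pos = pd.Series({m.marker_id: m.pos for m in pft.panel})
    chrom = pd.Series({m.marker_id: m.chrom for m in pft.panel})
    rows = []
    for c in sorted(chrom.unique()):
        ids = chrom.index[chrom == c]
        p = pos[ids].to_numpy()
        ia = pft.index.loc[ids, pop_a].to_numpy()
        ib = pft.index.loc[ids, pop_b].to_numpy()
        end = (chrom_lengths or {}).get(c, int(p.max()))
        start = 1
        while start <= end:
            w_end = min(start + window - 1, end)
            in_w = (p >= start) & (p < start + window)
            sel_a, sel_b = ia[in_w], ib[in_w]
            n_snps = int(in_w.sum())
            ma = float(np.nanmean(sel_a)) if n_snps and not np.all(np.isnan(sel_a)) else np.nan
            mb = float(np.nanmean(sel_b)) if n_snps and not np.all(np.isnan(sel_b)) else np.nan
            delta = abs(ma - mb) if not (np.isnan(ma) or np.isnan(mb)) else np.nan
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": w_end,
                    f"index_{pop_a}": ma,
                    f"index_{pop_b}": mb,
                    "delta": delta,
                    "n_snps": n_snps,
                }
            )
            if w_end >= end:
                break
            start += step
    return pd.DataFrame(rows)


def fixed_differences(
    pft: PopFreqTable,
    pop_a: str,
    pop_b: str,
    tol: float = 0.0,
    min_alleles: int = 10,
) -> list[str]:
    """Loci alternatively fixed between two populations: |idx_a - idx_b| >= 1 - tol.

    Loci where either population has fewer than ``min_alleles`` observed
    allele draws are not eligible (a fixed difference needs evidence).
    """
    ia = pft.index[pop_a]
    ib = pft.index[pop_b]
    enough = (pft.counts[pop_a] >= min_alleles) & (pft.counts[pop_b] >= min_alleles)
    delta = (ia - ib).abs()
    hit = enough & delta.notna() & (delta >= 1.0 - tol)
    return list(pft.index.index[hit])


@dataclass
class DiagnosticMarker:
    marker_id: str
    genotype: tuple  # the diagnostic unordered allele pair, e.g. ("A", "A")
    target_population: str
    sensitivity: float
    specificity: float
    counts: dict  # carriers/targets breakdown


def evaluate_diagnostic(
    markers: list[tuple[str, tuple]],
    matrix: GenotypeMatrix,
    labels,
    target_population: str,
) -> tuple[list[DiagnosticMarker], DiagnosticMarker]:
    """Sensitivity/specificity of diagnostic genotypes, singly and ANDed.

    ``markers`` is a list of (marker_id, diagnostic allele pair), e.g.
    ``[("MeSNP011", ("A", "A"))]``.  A variety *carries* the combination iff
    it has exactly the diagnostic (unordered) genotype at every listed
    marker; heterozygotes and missing calls do not count as carrying.

    sensitivity = carriers among target / target varieties;
    specificity = 1 - carriers among non-target / non-target varieties.
    """
    if isinstance(labels, dict):
        lab = [labels.get(v) for v in matrix.varieties]
    else:
        lab = list(labels)
    labelled = [i for i, l in enumerate(lab) if l is not None]
    is_target = np.array([lab[i] == target_population for i in labelled])

    def carrier_mask(marker_id: str, geno: tuple) -> np.ndarray:
        j = matrix.panel.index_of(marker_id)
        want = tuple(sorted(geno))
        return np.array(
            [matrix.cell(i, j) == want for i in labelled], dtype=bool
        )

    def make(mid: str, geno: tuple, carries: np.ndarray) -> DiagnosticMarker:
        n_t = int(is_target.sum())
        n_nt = int((~is_target).sum())
        tp = int((carries & is_target).sum())
        fp = int((carries & ~is_target).sum())
        return DiagnosticMarker(
            marker_id=mid,
            genotype=tuple(sorted(geno)),
            target_population=target_population,
            sensitivity=tp / n_t if n_t else float("nan"),
            specificity=1.0 - (fp / n_nt) if n_nt else float("nan"),
            counts={
                "n_target": n_t,
                "n_nontarget": n_nt,
                "carriers_target": tp,
                "carriers_nontarget": fp,
                "carriers_total": int(carries.sum()),
            },
        )

    singles = []
    combined_mask = np.ones(len(labelled), dtype=bool)
    for mid, geno in markers:
        mask = carrier_mask(mid, geno)
        combined_mask &= mask
        singles.append(make(mid, geno, mask))
    combined = make(
        "+".join(mid for mid, _ in markers),
        tuple(a for _, g in markers for a in sorted(g)),
        combined_mask,
    )
    return singles, combined
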