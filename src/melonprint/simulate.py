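"""Synthetic genotype, genome and variant-catalog generation.

Emulates the statistical structure of a commercial melon variety panel:
two deeply diverged subpopulations (thick-skinned ssp. melo-like "pop1" and
thin-skinned ssp. agrestis-like "pop2") plus admixed hybrids, mostly
homozygous varieties (heavy selfing), SSR loci with multi-allele ladders,
SNP loci with locus-specific missing rates, and a handful of planted
alternatively-fixed diagnostic SNPs.

Divergence follows the Balding-Nichols model: per locus an ancestral
frequency is drawn, and each subpopulation's frequency is a Beta (Dirichlet
for multi-allelic SSRs) draw around it with variance controlled by the
target fixation index F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import SNP, SSR, GenotypeMatrix, Marker, MarkerPanel

POP1, POP2, ADMIXED = "pop1", "pop2", "admixed"
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic variety panel.

    Defaults are the "melon-panel" preset: 259 diploid varieties
    (125 + 103 pure, 31 admixed), 129 SSR + 159 SNP loci on 12 chromosomes,
    strong subspecies divergence (F = 0.55), heavy selfing (s = 0.85, so
    most varieties are near-homozygous), SSR allele ladders of 2-15 alleles
    (mean about 5.3), SSR missing rates up to 0.29 and SNP missing rates up
    to 0.06, and 2 planted alternatively-fixed diagnostic SNPs.
    """

    n_pop1: int = 125
    n_pop2: int = 103
    n_admixed: int = 31
    n_ssr: int = 129
    n_snp: int = 159
    n_chrom: int = 12
    chrom_length: int = 3_000_000
    fst: float = 0.55
    selfing: float = 0.85
    ssr_allele_poisson_mean: float = 3.3  # alleles per SSR = 2 + Poisson(mean), <= 15
    ssr_max_alleles: int = 15
    ssr_missing_max: float = 0.29
    snp_missing_max: float = 0.06
    n_diagnostic: int = 2
    snp_freq_clip: float = 0.02  # keeps non-planted SNPs from incidental fixation
    snp_min_pooled_maf: float = 0.08  # panel ascertainment: SNPs segregate overall
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def melon_panel(seed: int = 0, **overrides) -> SimConfig:
    """The default preset mirroring the structure of the study panel."""
    return SimConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

@dataclass
class SimFrequencies:
    panel: MarkerPanel
    # per locus: dict with keys "alleles" (list) and "pop1"/"pop2"/"anc"
    # frequency vectors aligned to "alleles"
    loci: list[dict]
    diagnostic_ids: list[str]


def _bn_beta(rng, p: float, F: float) -> float:
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return float(rng.beta(a, b))


def _bn_dirichlet(rng, p: np.ndarray, F: float) -> np.ndarray:
    alpha = p * (1.0 - F) / F
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimFrequencies:
    """Draw ancestral and per-subpopulation allele frequencies for the panel.

    SNP subpopulation frequencies are clipped away from 0/1 (``snp_freq_clip``)
    so that, apart from the planted diagnostic loci, no marker is
    alternatively fixed between the subpopulations by chance: panel markers
    were ascertained to segregate.  Diagnostic loci are instead forced to
    reference-fixed in pop1 and alternative-fixed in pop2.
    """
    rng = rng or cfg.rng()
    # panel layout: random positions, sorted within chromosome
    chroms = [f"chr{c + 1:02d}" for c in range(cfg.n_chrom)]
    n_total = cfg.n_ssr + cfg.n_snp
    marker_chrom = rng.integers(0, cfg.n_chrom, size=n_total)
    marker_pos = rng.integers(1, cfg.chrom_length + 1, size=n_total)
    is_ssr = np.zeros(n_total, dtype=bool)
    is_ssr[rng.choice(n_total, size=cfg.n_ssr, replace=False)] = True
    order = np.lexsort((marker_pos, marker_chrom))
    motifs = ["AT", "AG", "AC", "AAG", "AAT", "ATC", "AAAT", "AGAT"]

    markers: list[Marker] = []
    loci: list[dict] = []
    n_ssr_seen = n_snp_seen = 0
    snp_indices: list[int] = []
    for rank, t in enumerate(order):
        chrom = chroms[marker_chrom[t]]
        pos = int(marker_pos[t])
        if is_ssr[t]:
            n_ssr_seen += 1
            mid = f"MeSSR{n_ssr_seen:03d}"
            k = 2 + int(rng.poisson(cfg.ssr_allele_poisson_mean))
            k = min(k, cfg.ssr_max_alleles)
            r0 = int(rng.integers(5, 30))
            alleles = list(range(r0, r0 + k))
            anc = rng.dirichlet(np.full(k, 1.5))
            # ascertainment: panel SSRs segregate, so at least two alleles
            # must remain common in the pooled panel; redraw until they do
            w1 = cfg.n_pop1 / (cfg.n_pop1 + cfg.n_pop2)
            for _ in range(100):
                p1 = _bn_dirichlet(rng, anc, cfg.fst)
                p2 = _bn_dirichlet(rng, anc, cfg.fst)
                pooled = w1 * p1 + (1 - w1) * p2
                if np.sum(pooled >= 0.05) >= 2:
                    break
            markers.append(Marker(mid, SSR, chrom, pos, motif=str(rng.choice(motifs))))
            loci.append(
                {"alleles": alleles, "anc": anc, POP1: p1, POP2: p2, "type": SSR}
            )
        else:
            n_snp_seen += 1
            mid = f"MeSNP{n_snp_seen:03d}"
            ref, alt = rng.choice(4, size=2, replace=False)
            clip = cfg.snp_freq_clip
            # ascertainment: panel SNPs were screened at MAF > 0.05, so the
            # pooled frequency must stay clear of fixation; redraw until it is
            w1 = cfg.n_pop1 / (cfg.n_pop1 + cfg.n_pop2)
            for _ in range(100):
                anc_p = float(rng.uniform(0.1, 0.9))
                p1 = min(max(_bn_beta(rng, anc_p, cfg.fst), clip), 1 - clip)
                p2 = min(max(_bn_beta(rng, anc_p, cfg.fst), clip), 1 - clip)
                pooled = w1 * p1 + (1 - w1) * p2
                if cfg.snp_min_pooled_maf <= pooled <= 1 - cfg.snp_min_pooled_maf:
                    break
            markers.append(Marker(mid, SNP, chrom, pos, ref=str(_BASES[ref])))
            loci.append(
                {
                    "alleles": [str(_BASES[ref]), str(_BASES[alt])],
                    "anc": np.array([anc_p, 1 - anc_p]),
                    POP1: np.array([p1, 1 - p1]),
                    POP2: np.array([p2, 1 - p2]),
                    "type": SNP,
                }
            )
            snp_indices.append(len(loci) - 1)
    # plant alternatively fixed diagnostic SNPs
    diag = sorted(rng.choice(snp_indices, size=cfg.n_diagnostic, replace=False).tolist())
    diag_ids = []
    for j in diag:
        loci[j][POP1] = np.array([1.0, 0.0])  # pop1 fixed reference
        loci[j][POP2] = np.array([0.0, 1.0])  # pop2 fixed alternative
        loci[j]["diagnostic"] = True
        diag_ids.append(markers[j].marker_id)
    return SimFrequencies(MarkerPanel(markers), loci, diag_ids)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class SimPanelData:
    matrix: GenotypeMatrix
    labels: list[str]  # pop1 / pop2 / admixed, aligned with matrix.varieties
    q: pd.DataFrame  # membership coefficients, columns pop1/pop2
    diagnostic_ids: list[str]
    config: SimConfig


def _draw_genotypes(rng, freq: np.ndarray, n: int, selfing: float) -> np.ndarray:
    """(n, 2) allele-index draws under inbreeding: with prob s the genotype is
    a homozygote for a single draw from freq, else two independent draws."""
    k = len(freq)
    g = rng.choice(k, size=(n, 2), p=freq)
    hom = rng.random(n) < selfing
    g[hom, 1] = g[hom, 0]
    return g


def simulate_genotypes(
    freqs: SimFrequencies, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimPanelData:
    """Sample the variety panel from per-subpopulation frequencies.

    Pure varieties draw from their subpopulation's frequencies with
    inbreeding coefficient ``selfing``; admixed varieties draw from a
    per-variety mixture q*pop1 + (1-q)*pop2 with q ~ U(0.35, 0.65), recorded
    in the Q table.  Missing calls are injected per locus at rates
    U(0, ssr_missing_max) / U(0, snp_missing_max); planted diagnostic loci
    stay fully observed (they emulate validated assay markers).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n1, n2, na = cfg.n_pop1, cfg.n_pop2, cfg.n_admixed
    n = n1 + n2 + na
    labels = [POP1] * n1 + [POP2] * n2 + [ADMIXED] * na
    names = (
        [f"V{POP1}{i + 1:03d}" for i in range(n1)]
        + [f"V{POP2}{i + 1:03d}" for i in range(n2)]
        + [f"Vadm{i + 1:03d}" for i in range(na)]
    )
    q_pure1 = rng.uniform(0.85, 0.99, size=n1)
    q_pure2 = 1.0 - rng.uniform(0.85, 0.99, size=n2)
    q_adm = rng.uniform(0.35, 0.65, size=na)
    q_all = np.concatenate([q_pure1, q_pure2, q_adm])
    q = pd.DataFrame({POP1: q_all, POP2: 1.0 - q_all}, index=names)

    m = len(freqs.panel)
    cells = [[None] * m for _ in range(n)]
    for j, locus in enumerate(freqs.loci):
        alleles = locus["alleles"]
        f1, f2 = locus[POP1], locus[POP2]
        g1 = _draw_genotypes(rng, f1, n1, cfg.selfing)
        g2 = _draw_genotypes(rng, f2, n2, cfg.selfing)
        ga = np.empty((na, 2), dtype=int)
        for x in range(na):
            fm = q_adm[x] * f1 + (1.0 - q_adm[x]) * f2
            fm = fm / fm.sum()
            ga[x] = _draw_genotypes(rng, fm, 1, cfg.selfing)[0]
        g = np.vstack([g1, g2, ga])
        # locus-specific missing rates: most loci genotype nearly completely,
        # a tail reaches the per-type maximum (right-skewed Beta profile)
        if locus.get("diagnostic"):
            miss_rate = 0.0
        elif locus["type"] == SSR:
            miss_rate = cfg.ssr_missing_max * rng.beta(1.2, 8.0)
        else:
            miss_rate = cfg.snp_missing_max * rng.beta(1.2, 8.0)
        missing = rng.random(n) < miss_rate
        for i in range(n):
            if missing[i]:
                continue
            a, b = g[i]
            cells[i][j] = (alleles[a], alleles[b])
    matrix = GenotypeMatrix(names, freqs.panel, cells)
    return SimPanelData(matrix, labels, q, freqs.diagnostic_ids, cfg)


def simulate_panel(cfg: SimConfig | None = None, seed: int | None = None) -> SimPanelData:
    """One-call generator: frequencies then genotypes, fully seeded."""
    cfg = cfg or melon_panel(seed if seed is not None else 0)
    if seed is not None:
        cfg.seed = seed
    rng = cfg.rng()
    freqs = simulate_frequencies(cfg, rng)
    return simulate_genotypes(freqs, cfg, rng)


# ---------------------------------------------------------------------------
# Toy genome + variant catalog for the discovery stage
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    contig_length: int = 16_000
    n_accessions: int = 20
    n_clean_ssr: int = 4
    n_contaminated_ssr: int = 2
    n_good_snp: int = 4
    n_bad_snp: int = 4  # one each: high_missing, high_het, low_maf, variant_in_flank
    duplicate_snp: bool = True  # add a non-unique-flank SNP via segmental duplication
    seed: int = 0


def _random_repeat_free(rng, length: int) -> str:
    """Random DNA with no 2-6-bp-motif tract of >= 3 copies (>= 8 bp run)."""
    from .discovery import PerfectFilterConfig, scan_ssrs

    seq = list(rng.choice(4, size=length))
    probe_cfg = PerfectFilterConfig(min_repeats={2: 3, 3: 3, 4: 2, 5: 2, 6: 2})
    for _ in range(50):
        s = "".join(_BASES[seq])
        hits = scan_ssrs({"c": s}, probe_cfg)
        # also break long homopolymers, which the SSR scanner ignores
        import re as _re

        homo = [m_.span() for m_ in _re.finditer(r"(.)\1{4,}", s)]
        if not hits and not homo:
            return s
        for loc in hits:
            for p in range(loc.start - 1, loc.end):
                seq[p] = int(rng.integers(0, 4))
        for a, b in homo:
            for p in range(a, b):
                seq[p] = int(rng.integers(0, 4))
    return "".join(_BASES[seq])


def simulate_genome_and_vcf(
    cfg: GenomeSimConfig | None = None,
    outdir=None,
    rng: np.random.Generator | None = None,
):
    """Build a toy genome with planted SSR tracts and SNPs plus its VCF.

    Returns (genome dict, vcf records, major-allele-frequency table,
    manifest dict); if ``outdir`` is given also writes genome.fa, variants.vcf,
    major_freq.csv and manifest.json there.
    """
    cfg = cfg or GenomeSimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    backbone = _random_repeat_free(rng, cfg.contig_length)
    seq = list(backbone)
    accessions = [f"acc{i + 1:02d}" for i in range(cfg.n_accessions)]

    manifest = {"ssr": [], "snp": []}
    vcf_records = []  # dicts: chrom,pos,ref,alt,gts
    slot = 600
    gap = 900  # planted features are spaced > 2x flank apart
    motif_choices = ["AG", "AT", "CT", "AAG", "ATC"]

    def plant_ssr(start: int, contaminated: bool):
        motif = str(rng.choice(motif_choices))
        n_rep = int(rng.integers(6, 10)) if len(motif) == 2 else int(rng.integers(5, 8))
        tract = motif * n_rep
        for i, base in enumerate(tract):
            seq[start - 1 + i] = base
        # spacer bases flanking the tract break its periodicity so the
        # scanned tract is exactly the planted one (not extended or shifted)
        k = len(motif)
        s0, e0 = start - 1, start - 2 + len(tract)  # 0-based tract span
        if s0 - 1 >= 0:
            seq[s0 - 1] = str(rng.choice([b for b in "ACGT" if b != seq[s0 - 1 + k]]))
        if e0 + 1 < len(seq):
            seq[e0 + 1] = str(rng.choice([b for b in "ACGT" if b != seq[e0 + 1 - k]]))
        rec = {
            "start": start,
            "end": start + len(tract) - 1,
            "motif": motif,
            "n_repeats": n_rep,
            "expect_pass": not contaminated,
            "reason": None,
        }
        if contaminated:
            vpos = start - 10  # SNP in the upstream flank
            ref = seq[vpos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            gts = ["0/0"] * cfg.n_accessions
            gts[0] = "1/1"
            vcf_records.append(
                {"pos": vpos, "ref": ref, "alt": alt, "gts": gts}
            )
            rec["reason"] = "variant_in_flank"
        manifest["ssr"].append(rec)

    def plant_snp(pos: int, kind: str):
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        nacc = cfg.n_accessions
        n_alt_hom = max(2, int(round(0.3 * nacc)))  # MAF ~0.3
        gts = ["1/1"] * n_alt_hom + ["0/0"] * (nacc - n_alt_hom)
        expect = True
        reason = None
        if kind == "high_missing":
            n_miss = int(np.ceil(0.15 * nacc))
            gts[-n_miss:] = ["./."] * n_miss
            expect, reason = False, "high_missing"
        elif kind == "high_het":
            n_het = int(np.ceil(0.25 * nacc))
            gts[:n_het] = ["0/1"] * n_het
            expect, reason = False, "high_het"
        elif kind == "low_maf":
            gts = ["1/1"] + ["0/0"] * (nacc - 1)  # MAF 0.05, not > 0.05
            expect, reason = False, "low_maf"
        elif kind == "variant_in_flank":
            vpos = pos + 15
            vref = seq[vpos - 1]
            valt = str(rng.choice([b for b in "ACGT" if b != vref]))
            nb = ["0/0"] * nacc
            nb[1] = "1/1"
            vcf_records.append({"pos": vpos, "ref": vref, "alt": valt, "gts": nb})
            expect, reason = False, "variant_in_flank"
        rng.shuffle(gts)
        vcf_records.append({"pos": pos, "ref": ref, "alt": alt, "gts": gts})
        manifest["snp"].append(
            {"pos": pos, "ref": ref, "alt": alt, "expect_pass": expect, "reason": reason}
        )

    cursor = slot
    for _ in range(cfg.n_clean_ssr):
        plant_ssr(cursor, contaminated=False)
        cursor += gap
    for _ in range(cfg.n_contaminated_ssr):
        plant_ssr(cursor, contaminated=True)
        cursor += gap
    for _ in range(cfg.n_good_snp):
        plant_snp(cursor, "good")
        cursor += gap
    for kind in ["high_missing", "high_het", "low_maf", "variant_in_flank"][: cfg.n_bad_snp]:
        plant_snp(cursor, kind)
        cursor += gap
    if cfg.duplicate_snp:
        plant_snp(cursor, "good")
        manifest["snp"][-1]["expect_pass"] = False
        manifest["snp"][-1]["reason"] = "flank_not_unique"
        a = cursor - 150
        b = cursor + 150
        dup = "".join(seq[a - 1 : b])
        seq.extend(list(dup))  # tandem copy at the contig end defeats uniqueness
        cursor += gap

    genome = {"chr01": "".join(seq)}
    vcf_records.sort(key=lambda r: r["pos"])

    # per-accession major-allele read frequency table for the SSR loci:
    # clean loci well above threshold; the last clean SSR gets one accession
    # below 0.7 so the read-support rule is exercised
    ssr_ids = [f"ssr_{r['start']}" for r in manifest["ssr"]]
    freq_tbl = pd.DataFrame(
        np.round(rng.uniform(0.85, 1.0, size=(len(ssr_ids), cfg.n_accessions)), 3),
        index=ssr_ids,
        columns=accessions,
    )
    if manifest["ssr"]:
        clean = [r for r in manifest["ssr"] if r["expect_pass"]]
        if clean:
            victim = clean[-1]
            freq_tbl.loc[f"ssr_{victim['start']}", accessions[0]] = 0.65
            victim["expect_pass"] = False
            victim["reason"] = "low_major_freq"

    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_vcf(vcf_records, genome, accessions, outdir / "variants.vcf")
        freq_tbl.to_csv(outdir / "major_freq.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return genome, vcf_records, freq_tbl, manifest


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(records, genome: dict[str, str], samples: list[str], path) -> None:
    """Write a minimal VCFv4.2 with GT fields (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, seq in genome.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in records:
            chrom = r.get("chrom", next(iter(genome)))
            fh.write(
                f"{chrom}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(r["gts"])
                + "\n"
            )
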