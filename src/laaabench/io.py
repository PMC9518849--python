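"""File interfaces: VCF, RFMix2 ``.msp.tsv``, plink genetic maps, phenotypes.

Simulated cohorts round-trip losslessly through a phased VCF 4.2 (genotypes)
plus an RFMix2-dialect ``.msp.tsv`` (local ancestry), so real data prepared
with standard tools can enter the association layer through the same paths.

Internal allele coding: allele 1 is the reference base (``REF``), allele 0
the alternate; VCF GT ``0`` therefore maps to internal allele 1.  Internal
coordinates are 0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import Cohort, LocalAncestryMatrix
from .presets import RecombinationMap

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_msp",
    "read_rfmix_msp",
    "write_cohort",
    "read_cohort",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "read_plink_genetic_map",
]


def write_vcf(cohort: Cohort, path: str | Path) -> Path:
    """Write phased genotypes as a plain-text VCF 4.2 file."""
    path = Path(path)
    hap = cohort.haplotypes
    n = cohort.n_individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=laaabench\n")
        for chrom, g in cohort.sites.groupby("chrom", sort=False):
            del g
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        chroms = cohort.sites["chrom"].to_numpy()
        poss = cohort.sites["pos"].to_numpy()
        ids = cohort.sites["id"].to_numpy()
        # GT allele: internal 1 (reference base) -> '0', internal 0 -> '1'
        gt_a = np.where(hap[0::2] == 1, "0", "1")
        gt_b = np.where(hap[1::2] == 1, "0", "1")
        for j in range(cohort.n_sites):
            fields = [
                str(chroms[j]),
                str(int(poss[j]) + 1),  # 1-based
                str(ids[j]),
                cohort.ref_allele,
                cohort.alt_allele,
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields.extend(gt_a[i, j] + "|" + gt_b[i, j] for i in range(n))
            fh.write("\t".join(fields) + "\n")
    return path


def read_vcf(path: str | Path):
    """Read a phased VCF into (sites, haplotypes, samples, ref, alt).

    Uses :mod:`cyvcf2`; only biallelic phased sites are supported.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    ref = alt = None
    for line_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: site {line_no}: expected biallelic site")
        ref, alt = var.REF, var.ALT[0]
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # back to 0-based
        ids.append(var.ID or f"snp{line_no - 1}")
        gts = np.asarray(var.genotypes)  # (n, 3): a, b, phased
        if gts.shape[1] < 3 or not np.all(gts[:, 2]):
            raise ValueError(f"{path}: site {line_no}: genotypes must be phased")
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"{path}: site {line_no}: missing genotype call")
        rows.append(gts[:, :2])
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    # stack to (2n, m): GT 0 = REF = internal allele 1
    gt = np.stack(rows, axis=-1)  # (n, 2, m)
    hap = (1 - gt.reshape(len(samples) * 2, -1)).astype(np.uint8)
    return sites, hap, samples, ref, alt


def _runs_of_constant_columns(codes: np.ndarray) -> np.ndarray:
    """Start indices of runs where no haplotype's label changes."""
    if codes.shape[1] == 0:
        return np.array([], dtype=int)
    change = np.any(codes[:, 1:] != codes[:, :-1], axis=0)
    return np.concatenate([[0], np.flatnonzero(change) + 1])


def write_msp(
    local: LocalAncestryMatrix,
    sites: pd.DataFrame,
    samples: list[str],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    cm_per_bp: float = 1e-6,
) -> Path:
    """Write per-site ancestry labels as an RFMix2-style ``.msp.tsv``.

    Rows are maximal intervals over which every haplotype's label is
    constant (0-based half-open ``spos``/``epos``); genetic positions use a
    uniform ``cm_per_bp`` scale.
    """
    path = Path(path)
    codes = local.codes
    header_codes = "\t".join(f"{s}={i}" for i, s in enumerate(local.sources))
    cols = [f"{s}.{h}" for s in samples for h in (0, 1)]
    # haplotype rows are (ind0 hapA, ind0 hapB, ind1 hapA, ...) already
    with open(path, "w") as fh:
        fh.write(f"#Subpopulation order/codes: {header_codes}\n")
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(cols) + "\n")
        offset = 0
        for chrom, group in sites.groupby("chrom", sort=False):
            pos = group["pos"].to_numpy()
            m_c = len(pos)
            block = codes[:, offset : offset + m_c]
            starts = _runs_of_constant_columns(block)
            ends = np.concatenate([starts[1:], [m_c]])
            chrom_end = (
                chrom_lengths[str(chrom)]
                if chrom_lengths is not None
                else int(pos[-1]) + 1
            )
            for s, e in zip(starts, ends):
                spos = int(pos[s])
                epos = int(pos[e]) if e < m_c else int(chrom_end)
                row = [
                    str(chrom),
                    str(spos),
                    str(epos),
                    f"{spos * cm_per_bp:.6f}",
                    f"{epos * cm_per_bp:.6f}",
                    str(e - s),
                ]
                row.extend(str(int(c)) for c in block[:, s])
                fh.write("\t".join(row) + "\n")
            offset += m_c
    return path


def read_rfmix_msp(
    path: str | Path,
    positions_by_chrom: dict[str, np.ndarray],
    samples: list[str] | None = None,
) -> tuple[LocalAncestryMatrix, list[str]]:
    """Expand an RFMix2 ``.msp.tsv`` to per-site labels.

    ``positions_by_chrom`` gives the 0-based site positions to expand onto;
    a site falls in a segment when ``spos <= pos < epos``.  The ancestry
    code map is taken from the header, so permuted code assignments are
    honored.  Unknown codes, overlapping segments and uncovered sites raise
    parse errors with line numbers.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2 or not lines[0].startswith("#Subpopulation order"):
        raise ValueError(f"{path}:1: missing subpopulation header")
    code_part = lines[0].split(":", 1)[1].strip()
    code_map: dict[int, str] = {}
    for tok in code_part.replace(",", "\t").split():
        name, code = tok.rsplit("=", 1)
        code_map[int(code)] = name.strip()
    sources = tuple(code_map[c] for c in sorted(code_map))
    recode = {c: i for i, c in enumerate(sorted(code_map))}

    header = lines[1].lstrip("#").rstrip("\n").split("\t")
    hap_cols = header[6:]
    col_samples = [c.rsplit(".", 1)[0] for c in hap_cols[0::2]]
    if samples is not None and col_samples != list(samples):
        raise ValueError(f"{path}:2: sample order mismatch")
    n_hap = len(hap_cols)

    m_total = sum(len(p) for p in positions_by_chrom.values())
    offsets, off = {}, 0
    for chrom, p in positions_by_chrom.items():
        offsets[chrom] = off
        off += len(p)
    codes = np.full((n_hap, m_total), -1, dtype=np.int8)
    last_epos: dict[str, int] = {}
    for line_no, line in enumerate(lines[2:], start=3):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6 + n_hap:
            raise ValueError(f"{path}:{line_no}: expected {6 + n_hap} columns")
        chrom, spos, epos = parts[0], int(parts[1]), int(parts[2])
        if chrom not in positions_by_chrom:
            raise ValueError(f"{path}:{line_no}: unknown chromosome {chrom!r}")
        if spos < last_epos.get(chrom, 0):
            raise ValueError(f"{path}:{line_no}: overlapping segment on {chrom}")
        last_epos[chrom] = epos
        pos = positions_by_chrom[chrom]
        lo = np.searchsorted(pos, spos, side="left")
        hi = np.searchsorted(pos, epos, side="left")
        if hi == lo:
            continue
        labels = np.empty(n_hap, dtype=np.int8)
        for h, tok in enumerate(parts[6:]):
            code = int(tok)
            if code not in recode:
                raise ValueError(f"{path}:{line_no}: unknown ancestry code {code}")
            labels[h] = recode[code]
        codes[:, offsets[chrom] + lo : offsets[chrom] + hi] = labels[:, None]
    if (codes < 0).any():
        raise ValueError(f"{path}: segments do not cover every site")
    return LocalAncestryMatrix(codes, sources), col_samples


def write_cohort(cohort: Cohort, vcf_path: str | Path, msp_path: str | Path):
    """Write a cohort as VCF + truth ``.msp.tsv``."""
    write_vcf(cohort, vcf_path)
    write_msp(cohort.truth, cohort.sites, cohort.samples, msp_path)
    return Path(vcf_path), Path(msp_path)


def read_cohort(
    vcf_path: str | Path, msp_path: str | Path, preset_name: str = "external"
) -> Cohort:
    """Rebuild a cohort from a VCF + ``.msp.tsv`` pair (inverse of
    :func:`write_cohort`, minus the generating tract lists)."""
    sites, hap, samples, ref, alt = read_vcf(vcf_path)
    positions = {
        str(c): g["pos"].to_numpy() for c, g in sites.groupby("chrom", sort=False)
    }
    truth, msp_samples = read_rfmix_msp(msp_path, positions, samples)
    if len(msp_samples) != len(samples):
        raise ValueError("VCF and msp sample counts differ")
    return Cohort(
        preset_name=preset_name,
        sources=truth.sources,
        sites=sites,
        haplotypes=hap,
        truth=truth,
        samples=samples,
        ref_allele=ref or "A",
        alt_allele=alt or "G",
    )


def write_phenotype_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a plink-style phenotype/covariate table (FID IID Y age sex)."""
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"FID", "IID", "Y"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_plink_genetic_map(
    paths_by_chrom: dict[str, str | Path], chrom_lengths: dict[str, int] | None = None
) -> RecombinationMap:
    """Read 3-column plink-style genetic maps (chrom, bp, cM) into a
    piecewise-constant recombination map (Morgans/bp)."""
    positions: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    for chrom, path in paths_by_chrom.items():
        tab = pd.read_csv(
            path, sep=r"\s+", header=None, names=["chrom", "bp", "cM"], comment="#"
        )
        bp = tab["bp"].to_numpy(dtype=float)
        cm = tab["cM"].to_numpy(dtype=float)
        if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
            raise ValueError(f"{path}: map positions must increase")
        if bp[0] > 0:
            bp = np.concatenate([[0.0], bp])
            cm = np.concatenate([[cm[0]], cm])
        end = float(chrom_lengths[chrom]) if chrom_lengths else bp[-1]
        if end > bp[-1]:
            bp = np.concatenate([bp, [end]])
            cm = np.concatenate([cm, [cm[-1]]])
        rate = np.diff(cm) / np.diff(bp) / 100.0  # cM -> Morgans
        positions[chrom] = bp
        rates[chrom] = rate
    return RecombinationMap(positions=positions, rates=rates)
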