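"""Trio-based phasing of F1 heterozygous SNVs.

A child heterozygous site is phased to maternal/paternal origin whenever at
least one parent is homozygous and exactly one Mendelian transmission
explains the child's genotype.  Sites where both parents are heterozygous
are ambiguous (either orientation is consistent) and sites with no legal
transmission are Mendelian errors; both classes are excluded from all
downstream allele assignment and reported in the summary.  Indels are not
phased — only SNVs feed the allele-specific read assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import VariantRecord

PHASED = "phased"
AMBIGUOUS = "ambiguous"
MENDELIAN_ERROR = "mendelian_error"


@dataclass
class TrioSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    child_gt: tuple[str, str]
    mother_gt: tuple[str, str]
    father_gt: tuple[str, str]


@dataclass
class PhasedHetSNV:
    chrom: str
    pos: int
    phase_status: str
    maternal_base: str | None = None
    paternal_base: str | None = None


@dataclass
class PhasingSummary:
    n_het: int
    n_phased: int
    n_ambiguous: int
    n_mendelian_error: int
    genome_size_kb: float | None = None

    @property
    def phased_fraction(self) -> float:
        return self.n_phased / self.n_het if self.n_het else float("nan")

    @property
    def snv_density_per_kb(self) -> float | None:
        """Phased SNVs per kb, given the genome-size parameter."""
        if self.genome_size_kb is None:
            return None
        return self.n_phased / self.genome_size_kb


def phase_site(site: TrioSite) -> PhasedHetSNV:
    """Phase one child-heterozygous site by Mendelian transmission.

    Requires all three genotypes (a missing genotype raises ``ValueError``,
    distinct from the ambiguous outcome).  Both-heterozygous parents give
    ``ambiguous``; impossible transmissions (including alleles absent from
    both parents) give ``mendelian_error``.
    """
    for name, gt in (("child", site.child_gt), ("mother", site.mother_gt),
                     ("father", site.father_gt)):
        if gt is None or len(gt) != 2:
            raise ValueError(f"missing {name} genotype at {site.chrom}:{site.pos}")
    child = frozenset(site.child_gt)
    if len(child) != 2:
        raise ValueError(
            f"phase_site requires a heterozygous child at {site.chrom}:{site.pos}")
    consistent = {
        (m, p)
        for m in site.mother_gt
        for p in site.father_gt
        if frozenset((m, p)) == child
    }
    if not consistent:
        return PhasedHetSNV(site.chrom, site.pos, MENDELIAN_ERROR)
    mother_hom = len(set(site.mother_gt)) == 1
    father_hom = len(set(site.father_gt)) == 1
    if not (mother_hom or father_hom):
        # both parents heterozygous: transmission orientation unresolvable
        return PhasedHetSNV(site.chrom, site.pos, AMBIGUOUS)
    assert len(consistent) == 1
    maternal, paternal = next(iter(consistent))
    return PhasedHetSNV(site.chrom, site.pos, PHASED, maternal, paternal)


def trio_sites_from_records(
    records: Iterable[VariantRecord],
    child: str,
    mother: str,
    father: str,
) -> list[TrioSite]:
    """Child-heterozygous SNV sites with complete trio genotypes.

    Indels, homozygous-child sites, and sites with any missing genotype are
    dropped (phasing is defined for heterozygous SNVs only).
    """
    sites = []
    for rec in records:
        if rec.kind != "snv":
            continue
        gts = [rec.genotypes.get(s) for s in (child, mother, father)]
        if any(g is None for g in gts):
            continue
        if len(set(gts[0])) != 2:
            continue
        sites.append(TrioSite(rec.chrom, rec.pos, rec.ref, rec.alt, *gts))
    return sites


def phase_all(
    sites: Sequence[TrioSite],
    genome_size_kb: float | None = None,
) -> tuple[pd.DataFrame, PhasingSummary]:
    """Phase every site; return the phase table and summary statistics.

    The summary reports the phased fraction (phased / heterozygous sites)
    and, when ``genome_size_kb`` is given, the phased-SNV density per kb.
    """
    rows = []
    for site in sites:
        out = phase_site(site)
        rows.append({
            "chrom": out.chrom,
            "pos": out.pos,
            "maternal_base": out.maternal_base,
            "paternal_base": out.paternal_base,
            "status": out.phase_status,
        })
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "maternal_base", "paternal_base",
                       "status"])
    counts = table["status"].value_counts()
    summary = PhasingSummary(
        n_het=len(table),
        n_phased=int(counts.get(PHASED, 0)),
        n_ambiguous=int(counts.get(AMBIGUOUS, 0)),
        n_mendelian_error=int(counts.get(MENDELIAN_ERROR, 0)),
        genome_size_kb=genome_size_kb,
    )
    return table, summary


def write_phase_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phase_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phased_vcf(sites: Sequence[TrioSite], phases: pd.DataFrame,
                     path, child: str = "child") -> None:
    """Write phased child genotypes as a single-sample VCF.

    Dialect: pipe-separated GT with the **maternal** allele first
    (``maternal|paternal``); unphased sites keep ``/``-separated GT.
    """
    status = dict(zip(zip(phases["chrom"], phases["pos"]),
                      zip(phases["status"], phases["maternal_base"])))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype, maternal allele first when phased">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{child}\n")
        for site in sites:
            st, maternal = status.get((site.chrom, site.pos), (None, None))
            if st == PHASED:
                gt = "0|1" if maternal == site.ref else "1|0"
            else:
                gt = "0/1"
            fh.write("\t".join([site.chrom, str(site.pos), ".", site.ref,
                                site.alt, ".", ".", ".", "GT", gt]) + "\n")
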