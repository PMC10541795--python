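"""Readers, writers, and threshold filters for the formats the pipeline touches.

Coordinate convention: every variant and annotation type in this package is
1-based with closed intervals.  Exported BED files (and only those) use the
0-based half-open BED convention; each writer that does so says so.

The VCF reader/writer here deliberately supports a restricted subset of
VCF 4.x (single-ALT SNVs/indels, GT plus a fixed set of numeric
annotations).  Values round-trip exactly through write/read, and parse
errors name the offending line.  Full VCF support (symbolic alleles,
breakends, phased-GT input, genotype likelihoods) is out of scope.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: INFO-level annotations recognised by the reader and the hard filter.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
#: FORMAT-level annotations folded to one site-level number.
#: GQ is the minimum across samples (conservative); DP prefers INFO DP and
#: otherwise sums the per-sample depths.
FORMAT_KEYS = ("GQ", "DP")
ANNOTATION_KEYS = INFO_KEYS + FORMAT_KEYS

#: Expression thresholds: a transcript counts as expressed when its mean TPM
#: across the libraries under consideration strictly exceeds the threshold
#: for its annotation class.
TPM_THRESHOLDS = {"PCG": 0.5, "lncRNA": 0.1, "TUCP": 0.1}

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One biallelic variant site with per-sample unordered genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    annotations: dict[str, float] = field(default_factory=dict)
    vid: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def kind(self) -> str:
        return "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass
class TranscriptModel:
    """Exon model of one transcript; exons are sorted 1-based closed intervals."""

    transcript_id: str
    gene_id: str
    transcript_type: str  # PCG | lncRNA | TUCP
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = ex

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base on '+', rightmost on '-'."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exon-union) length in bases."""
        return sum(e - s + 1 for s, e in self.exons)


class CountMatrix:
    """Transcript x library count matrix with optional effective lengths."""

    def __init__(
        self,
        counts: pd.DataFrame,
        effective_length: pd.Series | None = None,
    ) -> None:
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if effective_length is not None:
            effective_length = effective_length.reindex(counts.index)
            if effective_length.isna().any():
                raise ValueError("effective_length missing for some transcripts")
        self.counts = counts
        self.effective_length = effective_length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        same = self.counts.equals(other.counts)
        if self.effective_length is None or other.effective_length is None:
            return same and self.effective_length is other.effective_length
        return same and self.effective_length.equals(other.effective_length)

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        if self.effective_length is not None:
            df.insert(0, "effective_length", self.effective_length)
        df.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        eff = None
        if "effective_length" in df.columns:
            eff = df.pop("effective_length")
        return cls(df, eff)


DESIGN_COLUMNS = [
    "library_id", "individual_id", "family_id",
    "generation", "breed", "cross_direction", "tissue",
]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-design invariants: F0 rows carry a breed and no cross
    direction; F1 rows carry a cross direction (first symbol = sire breed)
    and no breed."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["library_id"].duplicated().any():
        raise ValueError("duplicate library_id in design")
    bad_gen = ~design["generation"].isin(["F0", "F1"])
    if bad_gen.any():
        raise ValueError(f"unknown generation labels: "
                         f"{design.loc[bad_gen, 'generation'].unique().tolist()}")
    f0 = design[design["generation"] == "F0"]
    f1 = design[design["generation"] == "F1"]
    if f0["breed"].isna().any() or not f0["cross_direction"].isna().all():
        raise ValueError("F0 rows must have breed and no cross_direction")
    if f1["cross_direction"].isna().any() or not f1["breed"].isna().all():
        raise ValueError("F1 rows must have cross_direction and no breed")
    bad_dir = ~f1["cross_direction"].isin(["AxB", "BxA"])
    if bad_dir.any():
        raise ValueError(f"unknown cross_direction labels: "
                         f"{f1.loc[bad_dir, 'cross_direction'].unique().tolist()}")
    return design


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"breed": "string",
                                            "cross_direction": "string"})
    df["breed"] = df["breed"].astype(object).where(df["breed"].notna(), np.nan)
    df["cross_direction"] = df["cross_direction"].astype(object).where(
        df["cross_direction"].notna(), np.nan)
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return repr(float(x))


def read_vcf_subset(path) -> list[VariantRecord]:
    """Parse a VCF 4.x subset into :class:`VariantRecord` objects.

    One record per biallelic site; multiallelic sites are skipped with a
    logged count.  Missing annotations stay absent (never coerced to 0).
    Malformed headers or rows raise ``ValueError`` naming the line number.
    """
    records: list[VariantRecord] = []
    samples: list[str] | None = None
    n_multi = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                               "FILTER", "INFO", "FORMAT"]:
                    raise ValueError(f"malformed VCF header at line {lineno}")
                samples = cols[9:]
                continue
            if samples is None:
                raise ValueError(f"VCF body before #CHROM header at line {lineno}")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise ValueError(
                    f"line {lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}"
                )
            chrom, pos_s, vid, ref, alt = cols[:5]
            if "," in alt:
                n_multi += 1
                continue
            if alt == "." or alt == ref:
                continue
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad POS {pos_s!r}") from exc
            annotations: dict[str, float] = {}
            if cols[7] != ".":
                for item in cols[7].split(";"):
                    if "=" not in item:
                        continue
                    key, _, val = item.partition("=")
                    if key in INFO_KEYS + ("DP",) and val != ".":
                        annotations[key] = float(val)
            fmt = cols[8].split(":")
            genotypes: dict[str, tuple[str, str] | None] = {}
            gqs: list[float] = []
            dps: list[float] = []
            for sample, sval in zip(samples, cols[9:]):
                fields = dict(zip(fmt, sval.split(":")))
                gt = fields.get("GT", "./.")
                alleles = re.split(r"[/|]", gt)
                if len(alleles) != 2 or "." in alleles:
                    genotypes[sample] = None
                else:
                    try:
                        pair = tuple(
                            (ref, alt)[int(a)] for a in alleles
                        )
                    except (ValueError, IndexError) as exc:
                        raise ValueError(
                            f"line {lineno}: bad GT {gt!r} for sample {sample}"
                        ) from exc
                    genotypes[sample] = pair  # type: ignore[assignment]
                if fields.get("GQ", ".") not in (".", ""):
                    gqs.append(float(fields["GQ"]))
                if fields.get("DP", ".") not in (".", ""):
                    dps.append(float(fields["DP"]))
            if gqs:
                annotations.setdefault("GQ", min(gqs))
            if dps and "DP" not in annotations:
                annotations["DP"] = float(sum(dps))
            records.append(VariantRecord(chrom, pos, ref, alt,
                                         genotypes, annotations, vid))
    if n_multi:
        logger.info("read_vcf_subset: skipped %d multiallelic site(s)", n_multi)
    return records


def write_vcf_subset(records: Sequence[VariantRecord], path,
                     samples: Sequence[str] | None = None) -> None:
    """Write records as a minimal VCF 4.2 file (GT:GQ:DP per sample)."""
    if samples is None:
        seen: dict[str, None] = {}
        for rec in records:
            for s in rec.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key in INFO_KEYS + ("DP",):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 + "".join("\t" + s for s in samples) + "\n")
        for rec in records:
            info = ";".join(
                f"{k}={_format_number(rec.annotations[k])}"
                for k in INFO_KEYS + ("DP", "GQ")
                if k in rec.annotations
            ) or "."
            gts = []
            for s in samples:
                gt = rec.genotypes.get(s)
                if gt is None:
                    gts.append("./.")
                else:
                    idx = ["0" if a == rec.ref else "1" for a in gt]
                    gts.append("/".join(idx))
            fh.write("\t".join([rec.chrom, str(rec.pos), rec.vid, rec.ref,
                                rec.alt, ".", ".", info, "GT"] + gts) + "\n")


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

#: (annotation, comparator, threshold).  A clause only fires when the
#: annotation is present (GATK semantics for absent annotations).
HARD_FILTER_CLAUSES = (
    ("QD", "lt", 10.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
    ("GQ", "lt", 30.0),
)

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$", re.IGNORECASE)


def is_autosome(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


def hard_filter_variants(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Apply the GATK-style hard-filter clauses plus the autosome restriction.

    A record is rejected iff at least one clause fires (strict inequalities;
    boundary values survive) or it lies on a sex chromosome, unplaced
    scaffold, or the mitochondrion (reason ``non-autosome``).  Returns
    ``(kept, rejected)`` where each rejected entry carries every firing
    clause name.
    """
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, list[str]]] = []
    for rec in records:
        reasons = [
            name for name, op, thr in HARD_FILTER_CLAUSES
            if name in rec.annotations
            and (rec.annotations[name] < thr if op == "lt"
                 else rec.annotations[name] > thr)
        ]
        if not is_autosome(rec.chrom):
            reasons.append("non-autosome")
        if reasons:
            rejected.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, rejected


def depth_filter(
    records: Sequence[VariantRecord],
    site_depths: Sequence[float],
    mode: str = "quantile",
) -> list[VariantRecord]:
    """Drop sites with extreme sequencing depth.

    ``quantile`` drops sites above the 99th or below the 1st percentile of
    the depth distribution; ``zscore`` drops |z| > 2.58 where z uses the
    sample mean/SD of depths.  With zero depth variance in zscore mode every
    site is kept (no information to reject on).
    """
    depths = np.asarray(site_depths, dtype=float)
    if len(depths) != len(records):
        raise ValueError("one depth per record required")
    if mode == "quantile":
        lo, hi = np.percentile(depths, [1, 99])
        keep = (depths >= lo) & (depths <= hi)
    elif mode == "zscore":
        if len(records) < 3:
            raise ValueError("zscore mode needs >= 3 records")
        sd = depths.std(ddof=1)
        if sd == 0:
            keep = np.ones(len(depths), dtype=bool)
        else:
            z = (depths - depths.mean()) / sd
            keep = np.abs(z) <= 2.58
    else:
        raise ValueError(f"unknown depth filter mode {mode!r}")
    return [rec for rec, k in zip(records, keep) if k]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def compute_tpm(matrix: CountMatrix) -> CountMatrix:
    """Transcripts-per-million from counts and effective lengths.

    Per library: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rates).
    A library with zero total rate yields an all-zero column with a warning.
    """
    if matrix.effective_length is None:
        raise ValueError("compute_tpm requires effective_length")
    lengths = matrix.effective_length.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective_length must be positive")
    rates = matrix.counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"libraries with no expression: "
            f"{list(matrix.counts.columns[zero])}", stacklevel=2)
        totals = np.where(zero, 1.0, totals)
    tpm = 1e6 * rates / totals
    return CountMatrix(
        pd.DataFrame(tpm, index=matrix.counts.index,
                     columns=matrix.counts.columns),
        matrix.effective_length,
    )


def expression_filter(
    tpm: pd.DataFrame,
    transcript_types: Mapping[str, str] | pd.Series,
    libraries: Sequence[str] | None = None,
) -> set[str]:
    """Transcripts whose mean TPM over ``libraries`` strictly exceeds the
    class threshold (0.5 for PCGs, 0.1 for lncRNAs/TUCPs)."""
    cols = tpm.columns if libraries is None else list(libraries)
    means = tpm[cols].mean(axis=1)
    out: set[str] = set()
    for tx, mean in means.items():
        ttype = transcript_types[tx]
        if ttype not in TPM_THRESHOLDS:
            raise ValueError(f"unknown transcript type {ttype!r} for {tx}")
        if mean > TPM_THRESHOLDS[ttype]:
            out.add(tx)
    return out


# ---------------------------------------------------------------------------
# annotation (GTF) and FASTA
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    Recognised attributes: transcript_id, gene_id, transcript_biotype
    (defaulting to PCG when absent).
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = cols
            if feature != "exon":
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"line {lineno}: exon without transcript_id")
            entry = exons.setdefault(tid, {
                "gene_id": a.get("gene_id", tid),
                "transcript_type": a.get("transcript_biotype", "PCG"),
                "chrom": chrom,
                "strand": strand,
                "exons": [],
            })
            entry["exons"].append((int(start), int(end)))
    return [
        TranscriptModel(transcript_id=tid, **entry)
        for tid, entry in exons.items()
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#!asecross transcript annotation\n")
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = (f'gene_id "{tx.gene_id}"; '
                         f'transcript_id "{tx.transcript_id}"; '
                         f'transcript_biotype "{tx.transcript_type}";')
                fh.write("\t".join([
                    tx.chrom, "asecross", "exon", str(start), str(end),
                    ".", tx.strand, ".", attrs,
                ]) + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write 1-based closed intervals as 0-based half-open BED records."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
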