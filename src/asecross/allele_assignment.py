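"""N-masking and allele-specific read assignment.

Heterozygous SNV positions are replaced with 'N' in the reference so that
neither allele enjoys a mapping advantage; aligned reads are then assigned
to the maternal (allele1) or paternal (allele2) haplotype by the bases they
carry at phased SNVs.  Reads voting for both haplotypes are ``conflicting``;
reads covering no phased SNV, or only third bases (sequencing errors), are
``unassignable``.  Conflicting reads are excluded from allele counts and
reported separately.

Counting is deterministic exon-union overlap: a read contributes one count
to every transcript whose exons its aligned blocks overlap (same
chromosome; strand ignored).  This replaces pseudoalignment quantification
so that counts are exactly checkable against simulation truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel

ALLELE1 = "allele1"  # maternal, or breed-A, per the design mapping
ALLELE2 = "allele2"
CONFLICTING = "conflicting"
UNASSIGNABLE = "unassignable"
LABELS = (ALLELE1, ALLELE2, CONFLICTING, UNASSIGNABLE)

#: column order of the per-library count blocks in an AlleleCountTable;
#: ``unassigned`` also absorbs reads not overlapping any transcript exon.
COUNT_LABELS = (ALLELE1, ALLELE2, CONFLICTING, "unassigned")


# ---------------------------------------------------------------------------
# genome masking
# ---------------------------------------------------------------------------

def mask_genome(
    genome: Mapping[str, str],
    phased_snvs: pd.DataFrame,
) -> dict[str, str]:
    """Replace each phased heterozygous SNV base with 'N'.

    ``phased_snvs`` needs columns chrom, pos (1-based) and, when available,
    maternal_base/paternal_base to sanity-check the reference base.
    Duplicate positions are masked once; out-of-range positions raise.
    """
    masked = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    have_bases = {"maternal_base", "paternal_base"} <= set(phased_snvs.columns)
    seen: set[tuple[str, int]] = set()
    n_dup = n_mismatch = 0
    for row in phased_snvs.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        if chrom not in masked:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= len(masked[chrom]):
            raise ValueError(f"SNV position {chrom}:{pos} out of range")
        if (chrom, pos) in seen:
            n_dup += 1
            continue
        seen.add((chrom, pos))
        if have_bases:
            ref_base = chr(masked[chrom][pos - 1]).upper()
            if ref_base not in (row.maternal_base, row.paternal_base, "N"):
                n_mismatch += 1
        masked[chrom][pos - 1] = ord("N")
    if n_dup:
        warnings.warn(f"{n_dup} duplicate SNV position(s) masked once",
                      stacklevel=2)
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} SNV(s) whose reference base matches neither allele",
            stacklevel=2)
    return {chrom: buf.decode("ascii") for chrom, buf in masked.items()}


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

class PhasedSnvIndex:
    """chrom -> {0-based position: (maternal_base, paternal_base)}."""

    def __init__(self, phase_table: pd.DataFrame) -> None:
        phased = phase_table[phase_table.get("status", "phased") == "phased"]
        self._by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
        for row in phased.itertuples(index=False):
            self._by_chrom.setdefault(row.chrom, {})[int(row.pos) - 1] = (
                row.maternal_base, row.paternal_base)

    def chrom(self, name: str) -> dict[int, tuple[str, str]]:
        return self._by_chrom.get(name, {})

    def __len__(self) -> int:
        return sum(len(d) for d in self._by_chrom.values())


@dataclass
class ReadAssignment:
    read_id: str
    label: str
    n_informative: int
    chrom: str
    blocks: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open


def assign_read(read, index: PhasedSnvIndex) -> ReadAssignment:
    """Assign one aligned read (pysam AlignedSegment or any object with the
    same ``reference_name`` / ``query_sequence`` / ``get_aligned_pairs`` /
    ``get_blocks`` surface) to a parental allele.

    Only match/mismatch-aligned bases are interrogated; insertions, clips,
    and skips never vote.  Reads on chromosomes without phased SNVs are
    unassignable, not an error.
    """
    chrom = read.reference_name
    sites = index.chrom(chrom)
    seq = read.query_sequence
    votes1 = votes2 = covered = 0
    if sites:
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            alleles = sites.get(rpos)
            if alleles is None:
                continue
            covered += 1
            base = seq[qpos].upper()
            if base == alleles[0]:
                votes1 += 1
            elif base == alleles[1]:
                votes2 += 1
    if votes1 and votes2:
        label, n_inf = CONFLICTING, votes1 + votes2
    elif votes1:
        label, n_inf = ALLELE1, votes1
    elif votes2:
        label, n_inf = ALLELE2, votes2
    else:
        label, n_inf = UNASSIGNABLE, 0
    return ReadAssignment(read.query_name, label, n_inf, chrom,
                          [(s, e) for s, e in read.get_blocks()])


def reconcile_pair(a: ReadAssignment, b: ReadAssignment) -> ReadAssignment:
    """Combine mate assignments: agreeing or one-informative pairs take the
    informative label; disagreeing informative mates become conflicting.
    The pair counts once, with the union of aligned blocks."""
    informative = {ALLELE1, ALLELE2}
    if a.label in informative and b.label in informative and a.label != b.label:
        label, n_inf = CONFLICTING, a.n_informative + b.n_informative
    elif CONFLICTING in (a.label, b.label):
        label, n_inf = CONFLICTING, a.n_informative + b.n_informative
    elif a.label in informative:
        label, n_inf = a.label, a.n_informative + b.n_informative
    elif b.label in informative:
        label, n_inf = b.label, a.n_informative + b.n_informative
    else:
        label, n_inf = UNASSIGNABLE, 0
    return ReadAssignment(a.read_id, label, n_inf, a.chrom,
                          sorted(a.blocks + b.blocks))


def assign_reads(reads: Iterable, index: PhasedSnvIndex,
                 paired: bool = False) -> list[ReadAssignment]:
    """Assign every read; with ``paired=True`` mates sharing a query name
    are reconciled into a single assignment."""
    assignments = [assign_read(r, index) for r in reads]
    if not paired:
        return assignments
    by_name: dict[str, list[ReadAssignment]] = {}
    order: list[str] = []
    for a in assignments:
        if a.read_id not in by_name:
            order.append(a.read_id)
        by_name.setdefault(a.read_id, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        merged = group[0]
        for other in group[1:]:
            merged = reconcile_pair(merged, other)
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

class AlleleCountTable:
    """Transcript x library counts split by allele label.

    Internally a DataFrame with MultiIndex columns (library, label) where
    label runs over allele1/allele2/conflicting/unassigned.  The TSV
    serialization flattens columns to ``library.label``.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        if (table.to_numpy() < 0).any():
            raise ValueError("allele counts must be non-negative")
        self.table = table

    @classmethod
    def empty(cls, transcripts: Sequence[str],
              libraries: Sequence[str]) -> "AlleleCountTable":
        cols = pd.MultiIndex.from_product([libraries, COUNT_LABELS],
                                          names=["library", "label"])
        return cls(pd.DataFrame(0, index=pd.Index(transcripts, name="transcript_id"),
                                columns=cols))

    @classmethod
    def from_alleles(cls, allele1: pd.DataFrame,
                     allele2: pd.DataFrame) -> "AlleleCountTable":
        """Build from two genes x libraries matrices (no conflicts/unassigned)."""
        out = cls.empty(list(allele1.index), list(allele1.columns))
        for lib in allele1.columns:
            out.table[(lib, ALLELE1)] = allele1[lib]
            out.table[(lib, ALLELE2)] = allele2[lib]
        return out

    @property
    def libraries(self) -> list[str]:
        return list(self.table.columns.get_level_values("library").unique())

    def allele_matrix(self, label: str) -> pd.DataFrame:
        """Genes x libraries matrix for one allele label."""
        sub = self.table.xs(label, axis=1, level="label")
        return sub

    def to_tsv(self, path) -> None:
        flat = self.table.copy()
        flat.columns = [f"{lib}.{label}" for lib, label in flat.columns]
        flat.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        flat = pd.read_csv(path, sep="\t", index_col="transcript_id")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit(".", 1)) for c in flat.columns],
            names=["library", "label"])
        flat.columns = cols
        return cls(flat)


def count_allele_reads(
    assignments: Sequence[ReadAssignment],
    transcripts: Sequence[TranscriptModel],
    library_id: str,
    existing: AlleleCountTable | None = None,
) -> AlleleCountTable:
    """Tally assignments into an allele count table for one library.

    A read contributes one count to every transcript whose exons overlap
    any of its aligned blocks on the same chromosome (strand ignored; reads
    spanning multiple genes count toward each).  Conflicting reads are
    tallied in their own column, never in the allele columns; assignable
    reads overlapping no exon land in ``unassigned``.
    """
    if existing is None:
        table = AlleleCountTable.empty([t.transcript_id for t in transcripts],
                                       [library_id])
    else:
        table = existing
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    col_of = {ALLELE1: ALLELE1, ALLELE2: ALLELE2,
              CONFLICTING: CONFLICTING, UNASSIGNABLE: "unassigned"}
    for a in assignments:
        label = col_of[a.label]
        hit_any = False
        for t in by_chrom.get(a.chrom, []):
            hit = any(
                bs < e and be > s - 1  # block [bs,be) vs exon [s-1,e)
                for bs, be in a.blocks
                for s, e in t.exons
            )
            if hit:
                hit_any = True
                table.table.loc[t.transcript_id, (library_id, label)] += 1
        if not hit_any and label in (ALLELE1, ALLELE2):
            pass  # read informative but outside annotation: not counted
    return table


def read_sam(path):
    """Iterate alignments from a SAM text file via pysam."""
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


def write_sam(reads: Sequence, references: Mapping[str, int], path) -> None:
    """Write simulated reads (anything with the pysam-like read surface plus
    ``cigarstring`` and 1-based ``pos``) as a SAM text file."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)}
               for name, length in references.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.query_name
            seg.reference_name = r.reference_name
            seg.reference_start = r.pos - 1
            seg.cigarstring = r.cigarstring
            seg.query_sequence = r.query_sequence
            seg.mapping_quality = 60
            seg.flag = 0
            seg.set_tag("XO", r.origin)
            out.write(seg)
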