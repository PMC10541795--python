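"""Synthetic reciprocal-cross experiments with known ground truth.

Every downstream stage of the pipeline (phasing, allele assignment,
imprinting calls, cis/trans classification) is testable against the truth
tables produced here, with no external data.

Generative model for the count experiment, per gene g with baseline
lambda_g ~ 2^Normal(baseline_log2_mean, baseline_log2_sd):

* F0 breed-A library mean  = lambda * 2^(c + t)
* F0 breed-B library mean  = lambda
* F1 breed-A allele mean   = (lambda / 2) * 2^c
* F1 breed-B allele mean   = lambda / 2

so that summed F1 expression matches the F0 scale.  c is the cis effect
and t the trans effect, both in log2 units.  Counts are negative binomial
with dispersion phi (variance = mu + phi * mu^2), scaled by per-library
size factors drawn uniformly in [0.7, 1.3].  Regulatory categories map to
(c, t) as: cis (c = +-e, t = 0); trans (c = 0, t = +-e); cis_plus_trans
(t = c); cis_times_trans (t = -2c, so the F0 and F1 ratios have equal
magnitude and opposite sign); compensatory (t = -c, F0 ratio zero);
conserved (c = t = 0).

The imprinting experiment draws per-library totals ~ NB(lambda, phi) and
splits them binomially with maternal probability rho (0.5 for biallelic
genes); the maternal/paternal origin maps to a breed allele through the
library's cross direction, so the maternally biased *breed* allele swaps
between reciprocal crosses while the parental bias does not.

All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import CountMatrix, TranscriptModel

CATEGORIES = ("cis", "trans", "cis_plus_trans", "cis_times_trans",
              "compensatory", "conserved")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic experiments.

    Defaults mirror the reciprocal-cross design under study: 4 replicates
    per F0 breed, 4 F1 hybrid libraries split evenly between cross
    directions, log2-normal baselines (mean 8, sd 2 -> median ~256 counts),
    NB dispersion 0.05, and a 2-log2-unit regulatory effect size.
    """

    seed: int = 0
    n_genes: int = 2400
    n_sites_per_gene: int = 3
    n_f0_replicates: int = 4          # per breed
    n_f1_replicates: int = 4          # total, split across directions
    n_per_direction: int = 3          # imprinting experiment
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.05
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {c: 1 / 6 for c in CATEGORIES})
    effect_size: float | tuple[float, ...] = 2.0  # |e| in log2 units; a
    # tuple draws each gene's magnitude uniformly from the set
    imprint_fraction: float = 0.25
    maternal_bias: float = 0.9        # rho for maternally imprinted genes
    read_depth: int = 10              # reads per allele per transcript
    base_error_rate: float = 0.01
    read_length: int = 80
    size_factor_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"category proportions sum to {total}, not 1")
        if set(self.category_proportions) - set(CATEGORIES):
            raise ValueError("unknown category in proportions")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.5 <= self.maternal_bias <= 1:
            raise ValueError("maternal_bias must lie in [0.5, 1]")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi*mu^2; Poisson when phi = 0."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    n = 1.0 / phi
    return rng.negative_binomial(n, n / (n + mu))


# ---------------------------------------------------------------------------
# trio genotypes
# ---------------------------------------------------------------------------

def simulate_trio_genotypes(
    n_sites: int,
    p_divergent: float,
    seed: int,
    shared_alt_freq: float = 0.3,
    chrom: str = "1",
    start: int = 1000,
    spacing: int = 200,
) -> pd.DataFrame:
    """Simulate biallelic SNV sites for one sire/dam/child trio.

    With probability ``p_divergent`` a site carries a fixed breed
    difference (sire breed homozygous ALT, dam breed homozygous REF);
    otherwise both parents draw alleles at the shared frequency
    ``shared_alt_freq``.  Child alleles follow Mendelian transmission; the
    truth columns record which base each parent transmitted.  The sire is
    taken as the father.
    """
    if not 0 <= p_divergent <= 1:
        raise ValueError("p_divergent must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows = []
    for i in range(n_sites):
        ref, alt = rng.choice(bases, size=2, replace=False)
        divergent = rng.random() < p_divergent
        if divergent:
            father = (alt, alt)
            mother = (ref, ref)
        else:
            f = shared_alt_freq
            father = tuple(np.where(rng.random(2) < f, alt, ref))
            mother = tuple(np.where(rng.random(2) < f, alt, ref))
        paternal = father[rng.integers(2)]
        maternal = mother[rng.integers(2)]
        rows.append({
            "chrom": chrom,
            "pos": start + i * spacing,
            "ref": ref,
            "alt": alt,
            "father_gt": "/".join(sorted(father)),
            "mother_gt": "/".join(sorted(mother)),
            "child_gt": "/".join(sorted((maternal, paternal))),
            "truth_maternal": maternal,
            "truth_paternal": paternal,
            "divergent": divergent,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele-specific reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    """A spliced, error-injected read with its truth allele of origin.

    Mirrors the fragment of the pysam AlignedSegment surface that the
    assignment code interrogates.
    """

    query_name: str
    reference_name: str
    pos: int                      # 1-based leftmost aligned base
    cigar_blocks: list[tuple[int, int]]  # 0-based half-open reference blocks
    query_sequence: str
    origin: str                   # 'maternal' | 'paternal'

    @property
    def cigarstring(self) -> str:
        parts = []
        prev_end = None
        for s, e in self.cigar_blocks:
            if prev_end is not None and s > prev_end:
                parts.append(f"{s - prev_end}N")
            parts.append(f"{e - s}M")
            prev_end = e
        return "".join(parts)

    def get_aligned_pairs(self, matches_only: bool = True):
        pairs = []
        q = 0
        for s, e in self.cigar_blocks:
            for r in range(s, e):
                pairs.append((q, r))
                q += 1
        return pairs

    def get_blocks(self) -> list[tuple[int, int]]:
        return list(self.cigar_blocks)


def random_genome(chrom_lengths: Mapping[str, int],
                  seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(rng.choice(bases, size=length))
        for chrom, length in chrom_lengths.items()
    }


def simulate_allelic_reads(
    phased_snvs: pd.DataFrame,
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    depth_per_allele: int,
    error_rate: float,
    seed: int,
    read_length: int = 80,
) -> list[SimulatedRead]:
    """Simulate exon-consistent reads from both haplotypes of a transcript.

    Each read is a spliced substring of the transcript carrying its
    haplotype's bases at phased SNVs; every base is independently replaced
    by a uniformly chosen different base with probability ``error_rate``.
    Raises if the read length exceeds the spliced transcript length.
    """
    L = transcript.length
    if read_length > L:
        raise ValueError(
            f"read length {read_length} exceeds transcript length {L}")
    rng = np.random.default_rng(seed)
    chrom_seq = genome[transcript.chrom]
    # transcript-coordinate -> reference-coordinate (0-based) lookup
    ref_pos = np.concatenate([
        np.arange(s - 1, e) for s, e in transcript.exons])
    phased = phased_snvs[phased_snvs["chrom"] == transcript.chrom]
    snv_bases = {
        int(r.pos) - 1: {"maternal": r.maternal_base, "paternal": r.paternal_base}
        for r in phased.itertuples(index=False)
    }
    haplotypes = {}
    for origin in ("maternal", "paternal"):
        seq = [
            snv_bases[rp][origin] if rp in snv_bases else chrom_seq[rp]
            for rp in ref_pos
        ]
        haplotypes[origin] = np.array(seq)
    other = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    reads: list[SimulatedRead] = []
    for origin in ("maternal", "paternal"):
        for i in range(depth_per_allele):
            tstart = int(rng.integers(0, L - read_length + 1))
            idx = np.arange(tstart, tstart + read_length)
            seq = haplotypes[origin][idx].copy()
            if error_rate > 0:
                errs = rng.random(read_length) < error_rate
                for j in np.flatnonzero(errs):
                    seq[j] = other[seq[j]][rng.integers(3)]
            rpos = ref_pos[idx]
            blocks: list[tuple[int, int]] = []
            bstart = rpos[0]
            prev = rpos[0]
            for rp in rpos[1:]:
                if rp != prev + 1:
                    blocks.append((int(bstart), int(prev) + 1))
                    bstart = rp
                prev = rp
            blocks.append((int(bstart), int(prev) + 1))
            reads.append(SimulatedRead(
                query_name=f"{transcript.transcript_id}:{origin}:{i}",
                reference_name=transcript.chrom,
                pos=int(rpos[0]) + 1,
                cigar_blocks=blocks,
                query_sequence="".join(seq),
                origin=origin,
            ))
    return reads


# ---------------------------------------------------------------------------
# count experiments
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    f0_counts: pd.DataFrame          # genes x (A then B libraries)
    f1_allele_a: pd.DataFrame        # genes x F1 libraries (breed-A allele)
    f1_allele_b: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame              # gene, category, cis/trans effects


def _draw_effects(rng: np.random.Generator, cfg: SimConfig,
                  n: int) -> pd.DataFrame:
    cats = rng.choice(
        CATEGORIES, size=n,
        p=[cfg.category_proportions[c] for c in CATEGORIES])
    sign = rng.choice([-1.0, 1.0], size=n)
    if np.isscalar(cfg.effect_size):
        e = float(cfg.effect_size)
    else:
        e = rng.choice(np.asarray(cfg.effect_size, dtype=float), size=n)
    c = np.zeros(n)
    t = np.zeros(n)
    c[cats == "cis"] = (e * sign)[cats == "cis"]
    t[cats == "trans"] = (e * sign)[cats == "trans"]
    m = cats == "cis_plus_trans"
    c[m] = (e * sign)[m]; t[m] = c[m]
    m = cats == "cis_times_trans"
    c[m] = (e * sign)[m]; t[m] = -2 * c[m]
    m = cats == "compensatory"
    c[m] = (e * sign)[m]; t[m] = -c[m]
    genes = [f"g{i:05d}" for i in range(n)]
    return pd.DataFrame({
        "gene_id": genes, "category": cats,
        "cis_effect": c, "trans_effect": t,
    }).set_index("gene_id")


def simulate_count_experiment(config: SimConfig) -> SimulatedCounts:
    """F0 breed counts and F1 breed-allele counts with per-gene truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_effects(rng, cfg, cfg.n_genes)
    lam = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                            cfg.n_genes)
    truth["baseline"] = lam
    c = truth["cis_effect"].to_numpy()
    t = truth["trans_effect"].to_numpy()
    lo, hi = cfg.size_factor_range
    n0, n1 = cfg.n_f0_replicates, cfg.n_f1_replicates
    sf0 = rng.uniform(lo, hi, 2 * n0)
    sf1 = rng.uniform(lo, hi, n1)
    f0_cols = [f"F0_A_{j + 1}" for j in range(n0)] + \
              [f"F0_B_{j + 1}" for j in range(n0)]
    f1_cols = [f"F1_{j + 1}" for j in range(n1)]
    mu_a = lam * 2.0 ** (c + t)
    mu_b = lam
    f0 = np.column_stack(
        [_nb_draw(rng, mu_a * sf0[j], cfg.dispersion) for j in range(n0)]
        + [_nb_draw(rng, mu_b * sf0[n0 + j], cfg.dispersion) for j in range(n0)])
    mu_f1a = lam / 2 * 2.0 ** c
    mu_f1b = lam / 2
    f1a = np.column_stack(
        [_nb_draw(rng, mu_f1a * sf1[j], cfg.dispersion) for j in range(n1)])
    f1b = np.column_stack(
        [_nb_draw(rng, mu_f1b * sf1[j], cfg.dispersion) for j in range(n1)])
    directions = ["AxB" if j % 2 == 0 else "BxA" for j in range(n1)]
    design = pd.DataFrame({
        "library_id": f0_cols + f1_cols,
        "individual_id": [f"ind_{c_}" for c_ in f0_cols + f1_cols],
        "family_id": ["fam0"] * (2 * n0) + [f"fam{1 + j % 2}" for j in range(n1)],
        "generation": ["F0"] * (2 * n0) + ["F1"] * n1,
        "breed": ["A"] * n0 + ["B"] * n0 + [np.nan] * n1,
        "cross_direction": [np.nan] * (2 * n0) + directions,
        "tissue": "muscle",
        "true_size_factor": np.concatenate([sf0, sf1]),
    })
    idx = truth.index
    return SimulatedCounts(
        f0_counts=pd.DataFrame(f0, index=idx, columns=f0_cols),
        f1_allele_a=pd.DataFrame(f1a, index=idx, columns=f1_cols),
        f1_allele_b=pd.DataFrame(f1b, index=idx, columns=f1_cols),
        design=design,
        truth=truth,
    )


@dataclass
class SimulatedImprinting:
    allele_a: pd.DataFrame           # breed-A allele counts, genes x libraries
    allele_b: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame              # gene, true_imprint, rho


def simulate_imprinting_experiment(config: SimConfig) -> SimulatedImprinting:
    """Reciprocal-cross allele counts with parent-of-origin truth.

    Per gene and library: total ~ NB(lambda * size_factor, phi), maternal ~
    Binomial(total, rho), paternal = total - maternal.  rho = 0.5 for
    biallelic genes, ``maternal_bias`` for maternally imprinted genes, and
    1 - maternal_bias for paternally imprinted ones.  The maternal count is
    reported as the breed-B allele in AxB libraries (sire = breed A) and as
    the breed-A allele in BxA libraries.
    """
    cfg = config
    if cfg.n_per_direction < 1:
        raise ValueError("both cross directions need >= 1 replicate")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    lam = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    status = rng.choice(
        ["none", "maternal", "paternal"], size=n,
        p=[1 - cfg.imprint_fraction, cfg.imprint_fraction / 2,
           cfg.imprint_fraction / 2])
    rho = np.where(status == "maternal", cfg.maternal_bias,
                   np.where(status == "paternal", 1 - cfg.maternal_bias, 0.5))
    libs = [f"F1_AxB_{j + 1}" for j in range(cfg.n_per_direction)] + \
           [f"F1_BxA_{j + 1}" for j in range(cfg.n_per_direction)]
    directions = ["AxB"] * cfg.n_per_direction + ["BxA"] * cfg.n_per_direction
    lo, hi = cfg.size_factor_range
    sf = rng.uniform(lo, hi, len(libs))
    allele_a = pd.DataFrame(index=genes, columns=libs, dtype=int)
    allele_b = pd.DataFrame(index=genes, columns=libs, dtype=int)
    for j, (lib, direction) in enumerate(zip(libs, directions)):
        total = _nb_draw(rng, lam * sf[j], cfg.dispersion)
        maternal = rng.binomial(total, rho)
        paternal = total - maternal
        if direction == "AxB":     # sire = A, so the A allele is paternal
            allele_a[lib], allele_b[lib] = paternal, maternal
        else:
            allele_a[lib], allele_b[lib] = maternal, paternal
    design = pd.DataFrame({
        "library_id": libs,
        "individual_id": [f"ind_{c}" for c in libs],
        "family_id": [f"fam_{d}" for d in directions],
        "generation": "F1",
        "breed": np.nan,
        "cross_direction": directions,
        "tissue": "muscle",
        "true_size_factor": sf,
    })
    truth = pd.DataFrame({"true_imprint": status, "rho": rho,
                          "baseline": lam}, index=genes)
    return SimulatedImprinting(allele_a, allele_b, design, truth)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _bundle_transcripts(rng: np.random.Generator, n_genes: int,
                        chrom_len: int, chrom: str = "1"
                        ) -> list[TranscriptModel]:
    """Evenly spaced 1-2 exon transcripts along one chromosome."""
    transcripts = []
    slot = chrom_len // n_genes
    types = ("PCG", "lncRNA", "TUCP")
    for i in range(n_genes):
        start = i * slot + 101
        n_exons = int(rng.integers(1, 3))
        if n_exons == 1:
            exons = [(start, start + 399)]
        else:
            exons = [(start, start + 199), (start + 300, start + 499)]
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(TranscriptModel(
            transcript_id=f"t{i:05d}", gene_id=f"g{i:05d}",
            transcript_type=types[i % 3], chrom=chrom,
            strand=strand, exons=exons))
    return transcripts


def write_fixture_bundle(outdir, config: SimConfig) -> dict[str, Path]:
    """Emit a complete, parseable mini-study to ``outdir``.

    Files: trio.vcf, genome_masked.fa, reads.sam, annotation.gtf,
    f0_counts.tsv, f1_allele_counts.tsv, design.tsv, truth.tsv.
    Re-running with the same config is byte-identical.
    """
    from . import allele_assignment, trio_phasing

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = replace(config, n_genes=min(config.n_genes, 60))
    rng = np.random.default_rng(cfg.seed)

    n_genes = cfg.n_genes
    chrom_len = n_genes * 1000
    transcripts = _bundle_transcripts(rng, n_genes, chrom_len)
    genome = random_genome({"1": chrom_len}, seed=cfg.seed + 1)

    # trio sites placed inside transcript exons
    site_rows = []
    for t in transcripts:
        exon = t.exons[0]
        for k in range(cfg.n_sites_per_gene):
            pos = exon[0] + 10 + 37 * k
            site_rows.append(pos)
    trio = simulate_trio_genotypes(
        len(site_rows), p_divergent=0.8, seed=cfg.seed + 2)
    trio["pos"] = site_rows
    trio["ref"] = [genome["1"][p - 1] for p in site_rows]
    # keep alt distinct from the reference base
    alts = []
    for ref, alt in zip(trio["ref"], trio["alt"]):
        alts.append(alt if alt != ref else {"A": "G", "G": "A",
                                            "C": "T", "T": "C"}[ref])
    trio["alt"] = alts

    # rebuild genotypes on the new ref/alt alphabet: divergent sites are
    # father alt/alt, mother ref/ref; others redrawn deterministically
    rng2 = np.random.default_rng(cfg.seed + 3)
    recs = []
    for r in trio.itertuples(index=False):
        if r.divergent:
            father, mother = (r.alt, r.alt), (r.ref, r.ref)
        else:
            f = 0.3
            father = tuple(np.where(rng2.random(2) < f, r.alt, r.ref))
            mother = tuple(np.where(rng2.random(2) < f, r.alt, r.ref))
        paternal = father[rng2.integers(2)]
        maternal = mother[rng2.integers(2)]
        recs.append(io_formats.VariantRecord(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            genotypes={"child": tuple(sorted((maternal, paternal))),
                       "mother": tuple(sorted(mother)),
                       "father": tuple(sorted(father))},
            annotations={"QD": 20.0, "FS": 1.0, "MQ": 60.0, "GQ": 99.0},
        ))
    vcf_path = outdir / "trio.vcf"
    io_formats.write_vcf_subset(recs, vcf_path,
                                samples=["child", "mother", "father"])

    sites = trio_phasing.trio_sites_from_records(
        recs, "child", "mother", "father")
    phase_table, _ = trio_phasing.phase_all(sites)

    masked = allele_assignment.mask_genome(
        genome, phase_table[phase_table["status"] == "phased"])
    fasta_path = outdir / "genome_masked.fa"
    io_formats.write_fasta(masked, fasta_path)

    reads = []
    for i, t in enumerate(transcripts[: min(10, n_genes)]):
        reads.extend(simulate_allelic_reads(
            phase_table[phase_table["status"] == "phased"], t, genome,
            depth_per_allele=cfg.read_depth,
            error_rate=cfg.base_error_rate,
            seed=cfg.seed + 10 + i, read_length=cfg.read_length))
    sam_path = outdir / "reads.sam"
    allele_assignment.write_sam(reads, {"1": chrom_len}, sam_path)

    gtf_path = outdir / "annotation.gtf"
    io_formats.write_gtf(transcripts, gtf_path)

    sim = simulate_count_experiment(cfg)
    f0_path = outdir / "f0_counts.tsv"
    CountMatrix(sim.f0_counts).to_tsv(f0_path)
    f1_path = outdir / "f1_allele_counts.tsv"
    allele_assignment.AlleleCountTable.from_alleles(
        sim.f1_allele_a, sim.f1_allele_b).to_tsv(f1_path)
    design_path = outdir / "design.tsv"
    sim.design.to_csv(design_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t")

    return {
        "vcf": vcf_path, "fasta": fasta_path, "sam": sam_path,
        "gtf": gtf_path, "f0_counts": f0_path, "f1_allele_counts": f1_path,
        "design": design_path, "truth": truth_path,
    }
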