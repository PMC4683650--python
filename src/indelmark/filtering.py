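"""Variant-call parsing, INDEL/SNP retention criteria and genome-wide summaries.

The retention rules mirror the standard resequencing marker-development
workflow: a call is *detected* when it passes site-quality criteria
(read depth, mapping quality, and for INDELs a minimum length that makes the
allele-size difference readable on a gel); heterozygous sites are then set
aside (an inbred line should be homozygous, so residual heterozygosity is
uninformative for marker design), and calls on unanchored assembly scaffolds
are excluded because they cannot be placed on a genetic map.  What remains is
the *retained* set from which markers are designed.

Zygosity is taken from the genotype (GT) field of the call, not inferred
from allele depths.  Input VCFs are assumed to be left-aligned/normalized by
the caller; this module does not re-normalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam

#: chromosome-name prefix reserved for unanchored assembly scaffolds
SCAFFOLD_PREFIX = "scaffold_"


@dataclass(frozen=True)
class VariantCall:
    """One called variant with site-quality annotations and zygosity.

    Positions are 1-based.  ``alts`` keeps every alternate allele of a
    multi-allelic record.  ``depth`` and ``mapping_quality`` may be ``None``
    when the source record lacked the canonical DP/MQ fields; such calls are
    flagged un-filterable and are never retained.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depth: int | None
    mapping_quality: float | None
    genotype: str  # "hom" (homozygous variant), "het", or "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not all(self.alts):
            raise ValueError("alleles must be non-empty")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.mapping_quality is not None and self.mapping_quality < 0:
            raise ValueError("mapping quality must be >= 0")

    @property
    def filterable(self) -> bool:
        """Whether the call carries the fields the retention criteria need."""
        return self.depth is not None and self.mapping_quality is not None

    @property
    def unanchored(self) -> bool:
        return self.chrom.startswith(SCAFFOLD_PREFIX)


@dataclass
class FilterCriteria:
    """Site-quality retention thresholds (all inclusive)."""

    min_depth: int = 5
    min_mapping_quality: float = 20.0
    min_indel_length: int = 5
    snp_reject_n: bool = True  # reject SNPs whose REF or ALT is an N
    snp_single_alt: bool = True  # reject multi-allelic SNP records

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_mapping_quality < 0 or self.min_indel_length < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class FilterSummary:
    """Bookkeeping of one INDEL filtering run.

    Conservation identities (asserted by :func:`filter_indels`):

    * ``homozygous == total_detected - heterozygous``
    * ``retained == homozygous - unanchored``
    * ``retained == retained_insertions + retained_deletions``
    """

    total_detected: int = 0
    heterozygous: int = 0
    homozygous: int = 0
    unanchored: int = 0
    retained: int = 0
    retained_insertions: int = 0
    retained_deletions: int = 0
    # filled in by summarize_genome
    per_chromosome: dict[str, int] = field(default_factory=dict)
    density_per_mb: float | None = None
    density_per_mb_full_assembly: float | None = None
    pericentromeric: int | None = None
    size_histogram: dict[int, int] = field(default_factory=dict)
    window_counts: pd.DataFrame | None = None

    def check_conservation(self) -> None:
        assert self.homozygous == self.total_detected - self.heterozygous
        assert self.retained == self.homozygous - self.unanchored
        assert self.retained == self.retained_insertions + self.retained_deletions
        if self.size_histogram:
            assert sum(self.size_histogram.values()) == self.retained

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_detected": self.total_detected,
                "heterozygous": self.heterozygous,
                "homozygous": self.homozygous,
                "unanchored": self.unanchored,
                "retained": self.retained,
                "retained_insertions": self.retained_insertions,
                "retained_deletions": self.retained_deletions,
            }
        )


def sequencing_yield_gb(n_reads: int, read_length_nt: int) -> int:
    """Raw sequencing yield of fixed-length reads, rounded to the nearest Gb."""
    return round(n_reads * read_length_nt / 1e9)


def conservation_counts(total_detected: int, heterozygous: int, unanchored: int) -> dict[str, int]:
    """Derive the homozygous and retained-anchored totals from detected counts.

    Pure integer bookkeeping: heterozygous calls are set aside first, then
    unanchored-scaffold calls are excluded from the homozygous remainder.
    """
    homozygous = total_detected - heterozygous
    retained = homozygous - unanchored
    return {"homozygous": homozygous, "retained_anchored": retained}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _genotype_code(gt: tuple | None) -> str:
    if gt is None or any(a is None for a in gt):
        return "other"
    alleles = set(gt)
    if alleles == {1}:
        return "hom"
    if 0 in alleles and len(alleles) > 1:
        return "het"
    return "other"


def read_variants(path: str) -> list[VariantCall]:
    """Read a VCF into :class:`VariantCall` records (positions stay 1-based).

    Multi-allelic records become one call carrying all ALT alleles.  Depth is
    taken from INFO/DP (falling back to the first sample's FORMAT/DP) and
    mapping quality from INFO/MQ.  A record missing either field yields a
    call with that field ``None`` — flagged un-filterable rather than
    silently retained.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                if rec.alts is None:
                    continue
                depth = rec.info.get("DP")
                if depth is None and rec.samples:
                    depth = next(iter(rec.samples.values())).get("DP")
                mq = rec.info.get("MQ")
                gt = None
                if rec.samples:
                    gt = next(iter(rec.samples.values())).get("GT")
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts),
                        depth=int(depth) if depth is not None else None,
                        mapping_quality=float(mq) if mq is not None else None,
                        genotype=_genotype_code(gt),
                    )
                )
            except (ValueError, KeyError) as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed VCF record #{i} at {rec.chrom}:{rec.pos}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(ref: str, alt: str) -> tuple[str, int]:
    """Classify one REF/ALT pair as ``snp`` / ``insertion`` / ``deletion`` / ``other``.

    Returns ``(kind, indel_length)`` where the length is ``|len(REF) - len(ALT)|``
    (0 for SNPs).  Equal-length multi-base substitutions are ``other`` and
    excluded from both the SNP and the INDEL stream.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "snp", 0
    if len(alt) > len(ref):
        return "insertion", len(alt) - len(ref)
    if len(ref) > len(alt):
        return "deletion", len(ref) - len(alt)
    return "other", 0


def classify_call(call: VariantCall) -> list[tuple[str, str, int]]:
    """Classify every ALT of a call; returns ``[(alt, kind, length), ...]``."""
    return [(alt, *classify(call.ref, alt)) for alt in call.alts]


def _best_indel_alt(call: VariantCall) -> tuple[str, str, int] | None:
    """The longest insertion/deletion ALT of a call, or None.

    Multi-allelic INDEL records are retained at most once per site; the
    longest qualifying ALT represents the locus.
    """
    indels = [(alt, kind, ln) for alt, kind, ln in classify_call(call) if kind in ("insertion", "deletion")]
    if not indels:
        return None
    return max(indels, key=lambda t: t[2])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_indels(
    calls: Iterable[VariantCall],
    criteria: FilterCriteria | None = None,
) -> tuple[list[VariantCall], FilterSummary]:
    """Apply the INDEL retention criteria and return (retained, summary).

    A call is *detected* when its best INDEL allele passes depth, mapping
    quality and minimum-length thresholds (all inclusive).  Detected
    heterozygous calls are counted and set aside; detected homozygous calls
    on unanchored scaffolds are counted and excluded; the remainder is
    retained.  The summary's conservation identities are asserted on every
    run.
    """
    criteria = criteria or FilterCriteria()
    summary = FilterSummary()
    retained: list[VariantCall] = []
    for call in calls:
        best = _best_indel_alt(call)
        if best is None:
            continue
        _, kind, length = best
        if not call.filterable:
            continue
        if call.depth < criteria.min_depth:
            continue
        if call.mapping_quality < criteria.min_mapping_quality:
            continue
        if length < criteria.min_indel_length:
            continue
        summary.total_detected += 1
        if call.genotype == "het":
            summary.heterozygous += 1
            continue
        summary.homozygous += 1
        if call.unanchored:
            summary.unanchored += 1
            continue
        summary.retained += 1
        if kind == "insertion":
            summary.retained_insertions += 1
        else:
            summary.retained_deletions += 1
        retained.append(call)
    summary.check_conservation()
    return retained, summary


def filter_snps(
    calls: Iterable[VariantCall],
    criteria: FilterCriteria | None = None,
) -> list[VariantCall]:
    """Apply the SNP retention criteria.

    Retained iff the record is a single-ALT SNP, depth and mapping quality
    pass the thresholds, and neither allele contains an N.  The
    single-variant-allele rule is applied per record, before any splitting.
    """
    criteria = criteria or FilterCriteria()
    retained: list[VariantCall] = []
    for call in calls:
        if criteria.snp_single_alt and len(call.alts) != 1:
            continue
        alt = call.alts[0]
        kind, _ = classify(call.ref, alt)
        if kind != "snp":
            continue
        if not call.filterable:
            continue
        if call.depth < criteria.min_depth:
            continue
        if call.mapping_quality < criteria.min_mapping_quality:
            continue
        if criteria.snp_reject_n and ("N" in call.ref.upper() or "N" in alt.upper()):
            continue
        retained.append(call)
    return retained


# ---------------------------------------------------------------------------
# genome-wide summaries
# ---------------------------------------------------------------------------

def summarize_genome(
    retained: Sequence[VariantCall],
    genome,
    summary: FilterSummary | None = None,
    window_size: int = 5_000_000,
    window_step: int | None = None,
) -> FilterSummary:
    """Extend a :class:`FilterSummary` with genome-wide distribution statistics.

    Computes per-chromosome counts, the average density per Mb (over the
    anchored chromosome length, and additionally over the full assembly
    length when the genome model declares one), sliding-window counts for
    plotting, pericentromeric membership (1-based inclusive interval
    containment), and the INDEL size histogram.

    Parameters
    ----------
    genome : GenomeModel
        Supplies chromosome lengths and pericentromeric intervals.
    window_size, window_step : int
        Sliding-window width and step in bp; the step defaults to the width
        (tiling windows).
    """
    summary = summary or FilterSummary(retained=len(retained))
    step = window_step or window_size
    per_chrom: dict[str, int] = {name: 0 for name in genome.chromosomes}
    sizes: dict[int, int] = {}
    peri = 0
    windows = []
    by_chrom: dict[str, list[int]] = {name: [] for name in genome.chromosomes}
    for call in retained:
        if call.chrom not in per_chrom:
            raise ValueError(f"call on {call.chrom!r} not anchored to the genome model")
        per_chrom[call.chrom] += 1
        by_chrom[call.chrom].append(call.pos)
        best = _best_indel_alt(call)
        if best is not None:
            sizes[best[2]] = sizes.get(best[2], 0) + 1
        interval = genome.pericentromere.get(call.chrom)
        if interval is not None and interval[0] <= call.pos <= interval[1]:
            peri += 1
    for name in genome.chromosomes:
        length = genome.lengths[name]
        positions = sorted(by_chrom[name])
        start = 1
        while start <= length:
            end = min(start + window_size - 1, length)
            n = sum(1 for p in positions if start <= p <= end)
            windows.append({"chrom": name, "start": start, "end": end, "count": n})
            if end == length:
                break
            start += step
    total_mb = sum(genome.lengths.values()) / 1e6
    summary.per_chromosome = per_chrom
    summary.density_per_mb = len(retained) / total_mb if total_mb else math.nan
    if getattr(genome, "total_assembly_length", None):
        summary.density_per_mb_full_assembly = len(retained) / (genome.total_assembly_length / 1e6)
    summary.pericentromeric = peri
    summary.size_histogram = dict(sorted(sizes.items()))
    summary.window_counts = pd.DataFrame(windows)
    return summary
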