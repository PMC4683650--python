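"""Gel-readable INDEL candidate selection and PCR primer design.

Candidates are the retained INDELs whose allele-size difference (5–50 bp)
can be resolved on a polyacrylamide gel.  Primer pairs are searched
deterministically in the flanks of each locus under the classic marker-lab
constraints: primer length 18–30 nt, GC 40–60 %, forward/reverse melting
temperatures within 3 °C, and product size 100–600 bp on both alleles.

The melting temperature uses the linear GC-fraction formula
``Tm = 64.9 + 41 * (nGC - 16.4) / N`` for an N-mer with nGC G/C bases — the
standard approximation for primers in the 18–30-mer range.  It is
deterministic and dependency-free; a nearest-neighbor model can be plugged
in through the ``tm`` argument of :func:`design_primers`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from indelmark.filtering import VariantCall, _best_indel_alt

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """GC content as a percentage: 100 x (G+C)/length."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(sequence: str) -> float:
    """Linear GC-fraction melting temperature, valid for primers >= 14 nt."""
    if len(sequence) < 14:
        raise ValueError("melting-temperature formula requires length >= 14")
    seq = sequence.upper()
    n_gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(sequence)


@dataclass
class PrimerConstraints:
    """Primer-design constraint box (all bounds inclusive)."""

    primer_len: tuple[int, int] = (18, 30)
    gc_percent: tuple[float, float] = (40.0, 60.0)
    max_tm_diff: float = 3.0
    product_size: tuple[int, int] = (100, 600)

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_len, self.gc_percent, self.product_size):
            if lo > hi:
                raise ValueError("constraint range is empty")

    def primer_ok(self, seq: str) -> bool:
        return (
            self.primer_len[0] <= len(seq) <= self.primer_len[1]
            and self.gc_percent[0] <= gc_content(seq) <= self.gc_percent[1]
        )


@dataclass
class PrimerPair:
    """A designed forward/reverse primer pair with its expected products.

    ``product_size_ref`` and ``product_size_alt`` are the amplicon sizes on
    the reference and alternate alleles; their absolute difference equals
    the INDEL length, which is what makes the marker scorable by size.
    ``forward_start`` / ``reverse_end`` are 1-based reference coordinates of
    the amplicon footprint.
    """

    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size_ref: int
    product_size_alt: int
    forward_start: int
    reverse_end: int

    def validate(self, constraints: PrimerConstraints, indel_length: int | None = None) -> None:
        """Re-check every constraint; raises ValueError on violation."""
        if not constraints.primer_ok(self.forward):
            raise ValueError("forward primer violates constraints")
        if not constraints.primer_ok(self.reverse):
            raise ValueError("reverse primer violates constraints")
        if abs(self.tm_forward - self.tm_reverse) > constraints.max_tm_diff:
            raise ValueError("Tm difference exceeds the maximum")
        for size in (self.product_size_ref, self.product_size_alt):
            if not constraints.product_size[0] <= size <= constraints.product_size[1]:
                raise ValueError("product size out of range")
        if indel_length is not None and abs(self.product_size_ref - self.product_size_alt) != indel_length:
            raise ValueError("allele product-size difference must equal the INDEL length")


@dataclass
class DesignFailure:
    """Explicit primer-design failure (not an exception)."""

    reason: str


@dataclass
class IndelMarker:
    """A candidate INDEL locus with (optionally) its designed primer pair."""

    marker_id: str
    chrom: str
    pos: int
    indel_length: int
    kind: str  # insertion | deletion
    primers: PrimerPair | None = None
    status: str = "candidate"  # candidate | validated-polymorphic | monomorphic | failed-amplification

    def __post_init__(self) -> None:
        if self.status == "candidate" and not (5 <= self.indel_length <= 50):
            raise ValueError("candidate INDEL length must be in [5, 50] bp")


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    retained: Iterable[VariantCall],
    min_len: int = 5,
    max_len: int = 50,
) -> list[VariantCall]:
    """Keep retained INDELs with length in [min_len, max_len], sorted by locus."""
    out = []
    for call in retained:
        best = _best_indel_alt(call)
        if best is None:
            continue
        if min_len <= best[2] <= max_len:
            out.append(call)
    return sorted(out, key=lambda c: (c.chrom, c.pos))


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

def design_primers(
    chrom_seq: str,
    pos: int,
    ref: str,
    alt: str,
    constraints: PrimerConstraints | None = None,
    tm: Callable[[str], float] = melting_temperature,
) -> PrimerPair | DesignFailure:
    """Design a primer pair bracketing a VCF-style anchored INDEL.

    The search is deterministic: forward-primer 3' ends walk outward
    (upstream) from the INDEL, primer lengths short-to-long; for each
    feasible forward primer, reverse-primer 5' ends walk outward downstream.
    The nearest feasible pair wins, which also yields the smallest product
    among ties.  The amplicon always contains the full INDEL site and both
    allele products must lie inside the product-size range.

    ``pos`` is 1-based; ``ref``/``alt`` follow the anchored VCF convention,
    so the variable site spans ``pos .. pos + len(ref) - 1`` on the
    reference.  Failure returns :class:`DesignFailure`, never raises.
    """
    constraints = constraints or PrimerConstraints()
    min_len, max_len = constraints.primer_len
    min_prod, max_prod = constraints.product_size
    indel_len = abs(len(ref) - len(alt))
    size_shift = len(alt) - len(ref)  # alt product minus ref product
    site_start = pos  # first reference base of the variable site
    site_end = pos + len(ref) - 1

    if site_start - 1 < max_prod // 2 or len(chrom_seq) - site_end < max_prod // 2:
        if site_start - 1 < min_prod // 2 or len(chrom_seq) - site_end < min_prod // 2:
            return DesignFailure("insufficient flank")

    seq = chrom_seq.upper()

    def forward_candidates():
        # 3' end walks upstream from just before the site
        for end in range(site_start - 1, 0, -1):
            for plen in range(min_len, max_len + 1):
                start = end - plen + 1
                if start < 1:
                    break
                primer = seq[start - 1: end]
                if constraints.primer_ok(primer):
                    yield start, end, primer
                    break  # nearest-first: one primer per 3'-end offset
            if site_start - end > max_prod:
                return

    for f_start, f_end, fwd in forward_candidates():
        tm_f = tm(fwd)
        # reverse primer 5' end walks downstream from just after the site
        for r_start in range(site_end + 1, len(seq) + 1):
            product_min_here = r_start + min_len - 1 - f_start + 1
            if product_min_here > max_prod:
                break
            found_rev = None
            for plen in range(min_len, max_len + 1):
                r_end = r_start + plen - 1
                if r_end > len(seq):
                    break
                template = seq[r_start - 1: r_end]
                rev = reverse_complement(template)
                if not constraints.primer_ok(rev):
                    continue
                tm_r = tm(rev)
                if abs(tm_f - tm_r) > constraints.max_tm_diff:
                    continue
                product_ref = r_end - f_start + 1
                product_alt = product_ref + size_shift
                if not (min_prod <= product_ref <= max_prod and min_prod <= product_alt <= max_prod):
                    continue
                found_rev = PrimerPair(
                    forward=fwd, reverse=rev,
                    tm_forward=tm_f, tm_reverse=tm_r,
                    gc_forward=gc_content(fwd), gc_reverse=gc_content(rev),
                    product_size_ref=product_ref, product_size_alt=product_alt,
                    forward_start=f_start, reverse_end=r_end,
                )
                break
            if found_rev is not None:
                found_rev.validate(constraints, indel_length=indel_len)
                return found_rev
    return DesignFailure("no feasible primer pair")


def design_marker(
    marker_id: str,
    chrom_seq: str,
    call: VariantCall,
    constraints: PrimerConstraints | None = None,
) -> IndelMarker | DesignFailure:
    """Design primers for a retained INDEL call and wrap it as a marker."""
    best = _best_indel_alt(call)
    if best is None:
        return DesignFailure("not an INDEL")
    alt, kind, length = best
    pair = design_primers(chrom_seq, call.pos, call.ref, alt, constraints)
    if isinstance(pair, DesignFailure):
        return pair
    return IndelMarker(
        marker_id=marker_id, chrom=call.chrom, pos=call.pos,
        indel_length=length, kind=kind, primers=pair,
    )


def markers_table(markers: Sequence[IndelMarker]) -> pd.DataFrame:
    """Flatten designed markers into the standard marker-table layout."""
    rows = []
    for m in markers:
        p = m.primers
        rows.append(
            {
                "marker_id": m.marker_id, "chrom": m.chrom, "pos": m.pos,
                "indel_length": m.indel_length, "kind": m.kind, "status": m.status,
                "forward": p.forward if p else None,
                "reverse": p.reverse if p else None,
                "tm_forward": p.tm_forward if p else None,
                "tm_reverse": p.tm_reverse if p else None,
                "gc_forward": p.gc_forward if p else None,
                "gc_reverse": p.gc_reverse if p else None,
                "product_size_ref": p.product_size_ref if p else None,
                "product_size_alt": p.product_size_alt if p else None,
                "footprint_start": p.forward_start if p else None,
                "footprint_end": p.reverse_end if p else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anchor and fine-scale set selection
# ---------------------------------------------------------------------------

def _max_min_spacing_subset(positions: Sequence[int], k: int) -> list[int]:
    """Indices of k positions maximizing the minimum adjacent gap.

    Exact: binary search over achievable gaps with a greedy-leftmost
    feasibility check (the classic max-min placement algorithm); among
    optima the leftmost greedy selection is returned, which is
    deterministic.
    """
    pos = np.asarray(sorted(positions))
    n = len(pos)
    if k >= n:
        return list(range(n))
    if k <= 1:
        return [0]

    def select(d: float) -> list[int]:
        chosen = [0]
        last = pos[0]
        for i in range(1, n):
            if pos[i] - last >= d:
                chosen.append(i)
                last = pos[i]
                if len(chosen) == k:
                    break
        return chosen

    gaps = sorted({float(b - a) for a in pos for b in pos if b > a})
    lo, hi = 0, len(gaps) - 1
    best = 0.0
    while lo <= hi:
        mid = (lo + hi) // 2
        if len(select(gaps[mid])) == k:
            best = gaps[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    return select(best)


def _largest_remainder(weights: Mapping[str, float], total: int, minimum: Mapping[str, int], cap: Mapping[str, int]) -> dict[str, int]:
    """Apportion ``total`` seats by weight with largest-remainder rounding,
    honoring per-key minima and caps (ties broken by key name)."""
    keys = sorted(weights)
    alloc = {key: min(minimum.get(key, 0), cap[key]) for key in keys}
    remaining = total - sum(alloc.values())
    if remaining <= 0:
        return alloc
    wsum = sum(weights[key] for key in keys)
    quota = {key: remaining * weights[key] / wsum for key in keys}
    for key in keys:
        take = min(int(quota[key]), cap[key] - alloc[key])
        alloc[key] += take
    leftover = total - sum(alloc.values())
    by_remainder = sorted(keys, key=lambda key: (-(quota[key] - int(quota[key])), key))
    i = 0
    while leftover > 0 and any(alloc[key] < cap[key] for key in keys):
        key = by_remainder[i % len(keys)]
        if alloc[key] < cap[key]:
            alloc[key] += 1
            leftover -= 1
        i += 1
    return alloc


def select_anchor_set(
    candidates: Sequence[IndelMarker],
    genome,
    target_count: int,
) -> list[IndelMarker]:
    """Choose an evenly spread genome-wide anchor-marker set.

    Seats are apportioned to chromosomes proportionally to length
    (largest-remainder rounding; every chromosome holding at least one
    designable candidate gets at least one anchor).  Within a chromosome the
    subset maximizing the minimum pairwise spacing is selected exactly.
    """
    by_chrom: dict[str, list[IndelMarker]] = {}
    for m in candidates:
        by_chrom.setdefault(m.chrom, []).append(m)
    if not by_chrom:
        return []
    if target_count >= len(candidates):
        return sorted(candidates, key=lambda m: (m.chrom, m.pos))
    weights = {c: float(genome.lengths.get(c, 1)) for c in by_chrom}
    minimum = {c: 1 for c in by_chrom}
    cap = {c: len(ms) for c, ms in by_chrom.items()}
    alloc = _largest_remainder(weights, target_count, minimum, cap)
    chosen: list[IndelMarker] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.pos)
        idx = _max_min_spacing_subset([m.pos for m in ms], alloc[chrom])
        chosen.extend(ms[i] for i in idx)
    return sorted(chosen, key=lambda m: (m.chrom, m.pos))


def densify_region(
    candidates: Iterable[IndelMarker],
    chrom: str,
    start: int,
    end: int,
) -> list[IndelMarker]:
    """All designable candidates inside [start, end] on ``chrom``, by position."""
    return sorted(
        (m for m in candidates if m.chrom == chrom and start <= m.pos <= end),
        key=lambda m: m.pos,
    )
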