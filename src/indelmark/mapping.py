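"""Recessive-locus mapping in an F2 population.

The workflow is the classic recessive-class strategy: confirm a 3:1
wild-type:mutant segregation with a chi-square test, then genotype the
phenotypically mutant plants (all homozygous for the causal allele) at
markers across the genome.  At a marker, a mutant plant homozygous for the
mutant-parent allele (code A) carries 0 recombinant gametes, a heterozygous
plant (H) carries 1, and a plant homozygous for the other parent's allele
(B) carries 2 — every non-missing plant contributes 2 informative gametes.
Markers near the causal locus show few recombinant gametes, and the locus
is delimited between the innermost flanking markers that still carry at
least one recombinant.

A run of markers that consistently fail to amplify inside the mapped
interval points to a genomic deletion carried by the mutant line; given the
sequenced boundary coordinates its span is end - start in bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: chi-square critical value at alpha = 0.05 with 1 degree of freedom
CHI2_CRITICAL_1DF = 3.841


@dataclass
class SegregationTest:
    """Goodness-of-fit of an observed mutant count to a Mendelian ratio."""

    n_mutant: int
    n_total: int
    expected_ratio: tuple[int, int]  # wild-type : mutant
    chi_square: float
    df: int
    p_value: float
    consistent: bool

    def summary(self) -> str:
        ratio = f"{self.expected_ratio[0]}:{self.expected_ratio[1]}"
        verdict = "consistent" if self.consistent else "inconsistent"
        return (
            f"{self.n_mutant} mutants of {self.n_total} plants; expected {ratio} -> "
            f"chi2 = {self.chi_square:.3f} (df {self.df}, p = {self.p_value:.3f}): "
            f"{verdict} with a single recessive locus"
        )


def segregation_chi_square(
    n_mutant: int,
    n_total: int,
    expected_ratio: tuple[int, int] = (3, 1),
) -> SegregationTest:
    """Chi-square test of mutant segregation against a Mendelian ratio.

    No continuity correction: chi2 = sum (obs - exp)^2 / exp over the two
    phenotype classes, df = 1.  The verdict is "consistent" iff the
    statistic does not exceed the 5% critical value 3.841.
    """
    if not 0 <= n_mutant <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_mutant <= n_total and n_total > 0")
    wild, mut = expected_ratio
    total_parts = wild + mut
    exp_mut = n_total * mut / total_parts
    exp_wild = n_total * wild / total_parts
    obs_wild = n_total - n_mutant
    chi2 = (n_mutant - exp_mut) ** 2 / exp_mut + (obs_wild - exp_wild) ** 2 / exp_wild
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(
        n_mutant=n_mutant, n_total=n_total, expected_ratio=expected_ratio,
        chi_square=chi2, df=1, p_value=p, consistent=chi2 <= CHI2_CRITICAL_1DF,
    )


# ---------------------------------------------------------------------------
# recombinant-gamete counting
# ---------------------------------------------------------------------------

_GAMETES_PER_CODE = {"A": 0, "H": 1, "B": 2}


def count_recombinant_gametes(genotypes: Iterable) -> tuple[int, int]:
    """Count (recombinant, informative) gametes at one marker over mutant plants.

    Codes: A = homozygous mutant-parent (0 recombinants), H = heterozygous
    (1), B = homozygous other-parent (2).  A missing genotype contributes
    neither recombinant nor informative gametes.
    """
    recombinant = informative = 0
    for code in genotypes:
        if pd.isna(code):
            continue
        code = str(code)
        if code not in _GAMETES_PER_CODE:
            raise ValueError(f"unknown genotype code {code!r}")
        recombinant += _GAMETES_PER_CODE[code]
        informative += 2
    return recombinant, informative


def linkage_scan(
    mutant_genotypes: pd.DataFrame,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker recombinant-gamete counts over the mutant class.

    ``mutant_genotypes``: plants x markers table of A/H/B/NaN codes, mutant
    plants only.  Returns one row per marker with ``recombinants``,
    ``informative`` and the recombination-fraction estimate, joined with
    ``marker_map`` (marker_id, chrom, pos) when given and sorted by
    ascending recombination fraction.
    """
    rows = []
    for marker_id in mutant_genotypes.columns:
        rec, inf = count_recombinant_gametes(mutant_genotypes[marker_id])
        rows.append(
            {
                "marker_id": marker_id,
                "recombinants": rec,
                "informative": inf,
                "fraction": rec / inf if inf else np.nan,
            }
        )
    scan = pd.DataFrame(rows)
    if marker_map is not None:
        scan = scan.merge(marker_map[["marker_id", "chrom", "pos"]], on="marker_id", how="left")
    return scan.sort_values("fraction", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# interval delimitation
# ---------------------------------------------------------------------------

@dataclass
class MappingInterval:
    """Chromosomal interval between the innermost recombinant-bearing flanks.

    A side without any recombinant-carrying marker beyond the minimum region
    is *open*: the corresponding marker/position is None and the length is
    undefined (NaN).
    """

    chrom: str
    left_marker: str | None
    left_pos: int | None
    right_marker: str | None
    right_pos: int | None

    @property
    def open_left(self) -> bool:
        return self.left_marker is None

    @property
    def open_right(self) -> bool:
        return self.right_marker is None

    @property
    def length(self) -> float:
        if self.open_left or self.open_right:
            return float("nan")
        return float(self.right_pos - self.left_pos)

    def summary(self) -> str:
        left = f"{self.left_marker} ({self.left_pos:,} bp)" if not self.open_left else "open"
        right = f"{self.right_marker} ({self.right_pos:,} bp)" if not self.open_right else "open"
        if self.open_left or self.open_right:
            return f"{self.chrom}: {left} .. {right} (open-ended)"
        kb = self.length / 1000.0
        return f"{self.chrom}: {left} .. {right}, {self.length:,.0f} bp ({kb:,.0f} kb)"


def delimit_interval(scan: pd.DataFrame, chrom: str | None = None) -> MappingInterval:
    """Delimit the causal interval from a linkage scan on one chromosome.

    The *minimum-recombinant region* is the contiguous run of markers
    sharing the smallest recombinant count (the run containing its first
    occurrence in position order).  The interval runs from the closest
    marker left of that region carrying >= 1 recombinant to the closest such
    marker on the right; a side with no such marker is flagged open rather
    than silently truncated.
    """
    df = scan
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    elif "chrom" in df.columns:
        if df["chrom"].nunique() > 1:
            raise ValueError("scan spans several chromosomes; pass chrom=")
    if "pos" not in df.columns:
        raise ValueError("scan must carry marker positions (merge a marker map)")
    df = df.sort_values("pos").reset_index(drop=True)
    if df.empty:
        raise ValueError("no markers on the requested chromosome")
    counts = df["recombinants"].to_numpy()
    minimum = counts.min()
    first = int(np.argmax(counts == minimum))
    run_start = run_end = first
    while run_start > 0 and counts[run_start - 1] == minimum:
        run_start -= 1
    while run_end < len(counts) - 1 and counts[run_end + 1] == minimum:
        run_end += 1

    left_marker = left_pos = None
    for i in range(run_start - 1, -1, -1):
        if counts[i] >= 1:
            left_marker = df.loc[i, "marker_id"]
            left_pos = int(df.loc[i, "pos"])
            break
    right_marker = right_pos = None
    for i in range(run_end + 1, len(counts)):
        if counts[i] >= 1:
            right_marker = df.loc[i, "marker_id"]
            right_pos = int(df.loc[i, "pos"])
            break
    chrom_name = chrom if chrom is not None else (df["chrom"].iloc[0] if "chrom" in df.columns else "")
    return MappingInterval(
        chrom=chrom_name,
        left_marker=left_marker, left_pos=left_pos,
        right_marker=right_marker, right_pos=right_pos,
    )


# ---------------------------------------------------------------------------
# deletion detection
# ---------------------------------------------------------------------------

@dataclass
class DeletionCandidate:
    """A candidate genomic deletion inferred from failed amplifications."""

    chrom: str
    marker_ids: list[str]
    first_marker_pos: int
    last_marker_pos: int
    start: int | None = None  # sequenced boundary, when known
    end: int | None = None

    @property
    def span_bp(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start

    @property
    def span_kb(self) -> int | None:
        return None if self.span_bp is None else round(self.span_bp / 1000)

    def summary(self) -> str:
        base = (
            f"{len(self.marker_ids)} consecutive failed markers on {self.chrom} "
            f"({self.first_marker_pos:,}-{self.last_marker_pos:,} bp)"
        )
        if self.span_bp is not None:
            base += f"; sequenced boundaries {self.start:,}-{self.end:,} bp, span {self.span_bp:,} bp (~{self.span_kb} kb)"
        return base


def deletion_span(start: int, end: int) -> tuple[int, int]:
    """Span between sequenced deletion boundaries: (bp, rounded kb)."""
    bp = end - start
    return bp, round(bp / 1000)


def detect_deletion(
    markers: pd.DataFrame,
    boundaries: tuple[int, int] | None = None,
) -> DeletionCandidate | None:
    """Report the longest run of consecutive failed-amplification markers.

    ``markers`` needs columns ``marker_id``, ``chrom``, ``pos`` and a
    boolean ``failed``; markers are considered in position order within one
    chromosome.  Returns None when no marker failed.  ``boundaries`` are
    sequenced deletion border coordinates, attached for span arithmetic.
    """
    if markers["chrom"].nunique() > 1:
        raise ValueError("detect_deletion works on a single chromosome")
    df = markers.sort_values("pos").reset_index(drop=True)
    failed = df["failed"].to_numpy(bool)
    if not failed.any():
        return None
    best_start = best_len = 0
    i = 0
    while i < len(failed):
        if failed[i]:
            j = i
            while j + 1 < len(failed) and failed[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
            i = j + 1
        else:
            i += 1
    run = df.iloc[best_start: best_start + best_len]
    candidate = DeletionCandidate(
        chrom=str(df["chrom"].iloc[0]),
        marker_ids=list(run["marker_id"]),
        first_marker_pos=int(run["pos"].iloc[0]),
        last_marker_pos=int(run["pos"].iloc[-1]),
    )
    if boundaries is not None:
        candidate.start, candidate.end = int(boundaries[0]), int(boundaries[1])
    return candidate


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class F2LinkageModel:
    """Interval mapping of a single recessive locus in an F2 population.

    Parameters
    ----------
    population : DataFrame
        Plants as rows; a ``phenotype`` column ("mutant" / "wild-type") and
        one A/H/B/NaN genotype column per marker.
    marker_map : DataFrame
        Columns ``marker_id``, ``chrom``, ``pos`` (1-based bp).
    """

    def __init__(self, population: pd.DataFrame, marker_map: pd.DataFrame):
        if "phenotype" not in population.columns:
            raise ValueError("population table needs a 'phenotype' column")
        known = set(marker_map["marker_id"])
        self.marker_cols = [c for c in population.columns if c in known]
        if not self.marker_cols:
            raise ValueError("no marker columns match the marker map")
        self.population = population
        self.marker_map = marker_map
        if not (population["phenotype"] == "mutant").any():
            raise ValueError("need at least one mutant plant to scan")

    @classmethod
    def from_tsv(cls, population_path, marker_map_path) -> "F2LinkageModel":
        pop = pd.read_csv(population_path, sep="\t", index_col=0, na_values=["NA"])
        marker_map = pd.read_csv(marker_map_path, sep="\t", na_values=["NA"])
        return cls(pop, marker_map)

    def fit(self) -> "F2LinkageResults":
        phenotype = self.population["phenotype"]
        n_total = int(phenotype.notna().sum())
        n_mutant = int((phenotype == "mutant").sum())
        segregation = segregation_chi_square(n_mutant, n_total)
        mutants = self.population.loc[phenotype == "mutant", self.marker_cols]
        scan = linkage_scan(mutants, self.marker_map)
        best_chrom = scan.iloc[0]["chrom"]
        interval = delimit_interval(scan, chrom=best_chrom)
        return F2LinkageResults(
            model=self, segregation=segregation, scan=scan,
            best_chromosome=str(best_chrom), interval=interval,
        )


@dataclass
class F2LinkageResults:
    """Fitted F2 linkage results: segregation test, scan table, interval."""

    model: F2LinkageModel
    segregation: SegregationTest
    scan: pd.DataFrame
    best_chromosome: str
    interval: MappingInterval

    def summary(self) -> str:
        top = self.scan.head(8).to_string(index=False)
        return "\n".join(
            [
                "F2 recessive-locus linkage summary",
                "==================================",
                self.segregation.summary(),
                "",
                f"best-linked chromosome: {self.best_chromosome}",
                "top markers (ascending recombination fraction):",
                top,
                "",
                "delimited interval: " + self.interval.summary(),
            ]
        )

    def plot(self, ax=None):
        """Mapping diagram: recombinant counts along the best chromosome."""
        import matplotlib.pyplot as plt

        scan = self.scan[self.scan["chrom"] == self.best_chromosome].sort_values("pos")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        pos_mb = scan["pos"] / 1e6
        ax.stem(pos_mb, scan["recombinants"])
        for _, row in scan.iterrows():
            ax.annotate(
                str(row["marker_id"]), (row["pos"] / 1e6, row["recombinants"]),
                textcoords="offset points", xytext=(0, 6), ha="center", fontsize=7, rotation=90,
            )
        if not (self.interval.open_left or self.interval.open_right):
            ax.axvspan(self.interval.left_pos / 1e6, self.interval.right_pos / 1e6,
                       color="tab:red", alpha=0.2, label="delimited interval")
            ax.legend(loc="upper right", fontsize=8)
        ax.set_xlabel(f"{self.best_chromosome} position (Mb)")
        ax.set_ylabel("recombinant gametes")
        return ax
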