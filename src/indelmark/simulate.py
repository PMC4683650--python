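"""Synthetic genomes, variant calls, cultivar panels and F2 populations.

Every input the pipeline consumes can be generated here with a known ground
truth, so each downstream stage is testable against an independent ledger.
The generator emits *variant calls* directly (no reads, no alignment): the
unit being emulated is the post-calling output of a resequencing workflow —
calls with per-site read depth and mapping-quality noise, a small
heterozygous fraction (residual heterozygosity in a nominally inbred line),
and a small fraction of calls landing on unanchored assembly scaffolds.

Default magnitudes are calibrated to a soybean-scale resequencing study:
roughly 5.2e-5 INDELs and 2.55e-4 SNPs per bp, ~0.09% heterozygous calls,
~1.3% unanchored calls, ~30x mean depth.  Crossovers in F2 gametes follow
the Haldane map function (no interference), whose closed form makes
recombination fractions checkable analytically.

One global seed is split deterministically per sub-generator (reference,
variants, panel, F2), so any module's output can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from indelmark.filtering import SCAFFOLD_PREFIX, VariantCall

_BASES = np.array(list("ACGT"))

# fixed stream ids so sub-generators are independent yet reproducible
_STREAMS = {"reference": 0, "variants": 1, "panel": 2, "f2": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def haldane_r(d_morgans) :
    """Haldane map function: recombination fraction r = (1 - e^(-2d)) / 2."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float))) / 2.0


# ---------------------------------------------------------------------------
# genome model and reference simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A multi-chromosome diploid genome skeleton.

    ``lengths`` maps chromosome name to length in bp; ``pericentromere``
    holds one 1-based inclusive low-recombination interval per chromosome;
    ``gc`` is the genome-wide GC fraction used for base sampling.
    ``total_assembly_length`` may exceed the summed chromosome lengths to
    represent unanchored scaffold sequence.
    """

    lengths: dict[str, int]
    pericentromere: dict[str, tuple[int, int]] = field(default_factory=dict)
    gc: float = 0.35
    total_assembly_length: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("chromosome names must be unique")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for name, (start, end) in self.pericentromere.items():
            if name not in self.lengths:
                raise ValueError(f"pericentromeric interval on unknown chromosome {name!r}")
            if not (1 <= start <= end <= self.lengths[name]):
                raise ValueError(f"pericentromeric interval {start}-{end} outside {name!r}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @classmethod
    def demo(cls, n_chromosomes: int = 2, length: int = 1_000_000, gc: float = 0.35) -> "GenomeModel":
        """A small genome with the middle third of each chromosome pericentromeric."""
        lengths = {f"chr{i + 1:02d}": length for i in range(n_chromosomes)}
        peri = {name: (length // 3 + 1, 2 * length // 3) for name in lengths}
        return cls(lengths=lengths, pericentromere=peri, gc=gc)


def simulate_reference(model: GenomeModel, seed: int = 0) -> dict[str, str]:
    """Draw one i.i.d. base sequence per chromosome at the model's GC fraction."""
    rng = _rng(seed, "reference")
    p = np.array([(1 - model.gc) / 2, model.gc / 2, model.gc / 2, (1 - model.gc) / 2])
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for name in model.chromosomes:
        idx = rng.choice(4, size=model.lengths[name], p=p)
        out[name] = codes[idx].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# variant-call simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Rates and noise laws for variant-call simulation.

    Depth is negative-binomial (mean ``depth_mean``, shape ``depth_shape``);
    mapping quality is a discretized normal clipped to [0, 60]; INDEL lengths
    follow a capped geometric decay starting at 1 bp (monotone decline with
    length).  ``seed`` fixes every downstream draw.
    """

    indel_rate: float = 5.2e-5
    snp_rate: float = 2.55e-4
    indel_length_p: float = 0.25
    max_indel_length: int = 60
    het_fraction: float = 43 / 49276
    unanchored_fraction: float = 620 / 49276
    depth_mean: float = 30.3
    depth_shape: float = 8.0
    mq_mean: float = 45.0
    mq_sd: float = 12.0
    snp_multiallelic_rate: float = 0.01
    snp_n_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indel_rate", "snp_rate", "het_fraction", "unanchored_fraction",
                     "indel_length_p", "snp_multiallelic_rate", "snp_n_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimulatedVariants:
    """Variant calls plus the ground-truth ledger they were generated from.

    The ledger is row-aligned with ``calls`` and records, for every emitted
    call, the truth fields (kind, length, zygosity, anchoring) and whether
    the call satisfies the INDEL / SNP retention criteria — computed here
    from the truth, independently of the filtering code.
    """

    calls: list[VariantCall]
    ledger: pd.DataFrame

    def __iter__(self):
        return iter((self.calls, self.ledger))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def simulate_variant_calls(
    reference: Mapping[str, str],
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SimulatedVariants:
    """Emit INDEL and SNP calls over a reference with site-quality noise.

    Each call carries a chromosome (or a reserved ``scaffold_`` name when the
    unanchored fraction strikes), a 1-based position, VCF-style anchored
    REF/ALT alleles, a depth draw, a mapping-quality draw and a zygosity.
    """
    config = config or SimulationConfig()
    rng = _rng(config.seed if seed is None else seed, "variants")
    records: list[dict] = []
    scaffold_counter = 0

    for chrom, seq in reference.items():
        L = len(seq)
        usable = L - config.max_indel_length - 2
        if usable < 1:
            raise ValueError(f"chromosome {chrom!r} too short for the configured INDEL lengths")
        n_indel = rng.binomial(usable, config.indel_rate)
        n_snp = rng.binomial(usable, config.snp_rate)
        n_total = n_indel + n_snp
        if n_total == 0:
            continue
        positions = rng.choice(np.arange(2, usable + 2), size=min(n_total, usable), replace=False)
        indel_pos, snp_pos = positions[:n_indel], positions[n_indel:]

        for pos in sorted(int(p) for p in indel_pos):
            length = int(min(rng.geometric(config.indel_length_p), config.max_indel_length))
            if rng.random() < 0.5:
                kind = "deletion"
                ref = seq[pos - 1: pos + length]
                alt = seq[pos - 1]
            else:
                kind = "insertion"
                ref = seq[pos - 1]
                alt = ref + _random_bases(rng, length, 0.5)
            records.append(_site(rng, config, chrom, pos, ref, (alt,), kind, length))

        for pos in sorted(int(p) for p in snp_pos):
            ref = seq[pos - 1]
            others = [b for b in "ACGT" if b != ref]
            alt = others[int(rng.integers(3))]
            alts = (alt,)
            if rng.random() < config.snp_multiallelic_rate:
                second = [b for b in others if b != alt][int(rng.integers(2))]
                alts = (alt, second)
            if rng.random() < config.snp_n_rate:
                alts = ("N",)
            records.append(_site(rng, config, chrom, pos, ref, alts, "snp", 0))

    # unanchored relabeling, drawn per call
    for rec in records:
        if rng.random() < config.unanchored_fraction:
            scaffold_counter += 1
            rec["chrom"] = f"{SCAFFOLD_PREFIX}{scaffold_counter:05d}"
            rec["unanchored"] = True

    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    calls = [
        VariantCall(
            chrom=r["chrom"], pos=r["pos"], ref=r["ref"], alts=r["alts"],
            depth=r["depth"], mapping_quality=r["mq"], genotype=r["genotype"],
        )
        for r in records
    ]
    ledger = pd.DataFrame(records)
    if not ledger.empty:
        ledger["alts"] = ledger["alts"].map(lambda a: ",".join(a))
        # anchoring is decided after site generation, so re-derive here
        ledger["eligible_indel"] = ledger["eligible_indel"] & ~ledger["unanchored"]
    return SimulatedVariants(calls=calls, ledger=ledger)


def _site(rng, config, chrom, pos, ref, alts, kind, length) -> dict:
    depth_p = config.depth_shape / (config.depth_shape + config.depth_mean)
    depth = int(rng.negative_binomial(config.depth_shape, depth_p))
    mq = float(np.clip(np.round(rng.normal(config.mq_mean, config.mq_sd)), 0, 60))
    genotype = "het" if rng.random() < config.het_fraction else "hom"
    quality_ok = depth >= 5 and mq >= 20
    has_n = any("N" in a for a in alts) or "N" in ref
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alts": alts,
        "kind": kind,
        "indel_length": length,
        "depth": depth,
        "mq": mq,
        "genotype": genotype,
        "unanchored": False,
        "has_n": has_n,
        "n_alts": len(alts),
        # truth-side retention verdicts, written at generation time
        "detected_indel": kind in ("insertion", "deletion") and quality_ok and length >= 5,
        "eligible_indel": (
            kind in ("insertion", "deletion") and quality_ok and length >= 5
            and genotype == "hom"
        ),
        "eligible_snp": kind == "snp" and quality_ok and len(alts) == 1 and not has_n,
    }


# ---------------------------------------------------------------------------
# cultivar-panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelScenario:
    """A simulated marker x cultivar amplicon-size panel with ground truth.

    ``genotypes``: DataFrame (markers x cultivars) of amplicon sizes in bp,
    NaN meaning no amplification.  ``markers``: per-marker metadata including
    the primer-binding footprint.  ``truth``: per-marker allele counts and
    third-allele flags as generated.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame
    truth: pd.DataFrame


def simulate_panel(
    markers: pd.DataFrame,
    n_cultivars: int = 14,
    third_allele_rate: float = 14 / 165,
    missing_rate: float = 0.02,
    seed: int = 0,
    cultivar_names: Sequence[str] | None = None,
) -> PanelScenario:
    """Simulate amplicon-size genotypes of inbred cultivars at INDEL markers.

    The first cultivar carries the reference-parent allele and the second
    the alternate-parent allele at every marker (the two parents of the
    marker system); remaining cultivars draw either allele uniformly.  With
    probability ``third_allele_rate`` a marker segregates a third product
    size, assigned to one to four of the other cultivars.  Each cell then
    fails to amplify independently with probability ``missing_rate``.

    ``markers`` needs columns ``marker_id``, ``product_size_ref`` and
    ``product_size_alt`` (footprint columns are carried through if present).
    """
    if n_cultivars < 2:
        raise ValueError("need at least 2 cultivars")
    if not len(markers):
        raise ValueError("need at least 1 marker")
    rng = _rng(seed, "panel")
    names = list(cultivar_names) if cultivar_names is not None else [
        f"cultivar{c + 1:02d}" for c in range(n_cultivars)
    ]
    if len(names) != n_cultivars:
        raise ValueError("cultivar_names length must equal n_cultivars")

    marker_ids = list(markers["marker_id"])
    sizes_ref = markers["product_size_ref"].to_numpy(float)
    sizes_alt = markers["product_size_alt"].to_numpy(float)
    n_markers = len(marker_ids)

    pick_alt = rng.random((n_markers, n_cultivars)) < 0.5
    geno = np.where(pick_alt, sizes_alt[:, None], sizes_ref[:, None])
    geno[:, 0] = sizes_ref
    geno[:, 1] = sizes_alt

    third = np.zeros(n_markers, dtype=bool)
    if n_cultivars >= 3:
        third = rng.random(n_markers) < third_allele_rate
        for m in np.flatnonzero(third):
            delta = sizes_alt[m] - sizes_ref[m]
            offset = float(rng.integers(3, 11))
            if offset == delta:
                offset += 1.0
            third_size = sizes_ref[m] + offset if sizes_ref[m] + offset > 0 else sizes_ref[m] + offset + 20
            k = int(rng.integers(1, min(4, n_cultivars - 2) + 1))
            cols = rng.choice(np.arange(2, n_cultivars), size=k, replace=False)
            geno[m, cols] = third_size

    missing = rng.random((n_markers, n_cultivars)) < missing_rate
    geno = geno.astype(float)
    geno[missing] = np.nan

    genotypes = pd.DataFrame(geno, index=marker_ids, columns=names)
    truth = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "has_third_allele": third,
            "n_alleles_true": np.where(third, 3, 2),
            "n_missing": missing.sum(axis=1),
        }
    ).set_index("marker_id")
    return PanelScenario(genotypes=genotypes, markers=markers.reset_index(drop=True), truth=truth)


# ---------------------------------------------------------------------------
# F2 population simulation
# ---------------------------------------------------------------------------

@dataclass
class F2SimSpec:
    """Design of a simulated F2 population segregating one recessive locus.

    ``marker_map`` is a DataFrame with columns ``marker_id``, ``chrom``,
    ``pos`` (bp).  The phenotype is mutant iff a plant is homozygous for the
    mutant-parent allele at the causal locus; with a 3:1 wild:mutant
    expectation the mutant fraction is 1/4.  ``cm_per_mb`` converts physical
    to genetic distance; crossovers follow the Haldane model.
    """

    marker_map: pd.DataFrame
    causal_chrom: str
    causal_pos: int
    chrom_lengths: dict[str, int]
    cm_per_mb: float = 2.5
    n_plants: int = 511
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("population size must be > 0")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(f"causal locus chromosome {self.causal_chrom!r} not in the genome")
        if not (1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]):
            raise ValueError("causal locus position outside its chromosome")


@dataclass
class F2Scenario:
    """Simulated F2 genotypes/phenotypes plus the generating truth."""

    genotypes: pd.DataFrame  # plants x markers, codes A/H/B or NaN
    phenotypes: pd.Series  # "mutant" / "wild-type"
    marker_map: pd.DataFrame
    spec: F2SimSpec

    def table(self) -> pd.DataFrame:
        out = self.genotypes.copy()
        out.insert(0, "phenotype", self.phenotypes)
        return out


def _chain_gametes(
    rng: np.random.Generator,
    positions_bp: np.ndarray,
    cm_per_mb: float,
    n_gametes: int,
    anchor_idx: int | None = None,
) -> np.ndarray:
    """Simulate gamete alleles (0/1) along one chromosome as a Markov chain.

    Adjacent loci recombine with the Haldane fraction of their genetic
    distance.  With ``anchor_idx`` set, that locus is fixed to allele 1
    (mutant-parent) and the chain is propagated outward in both directions —
    i.e. the gamete is conditioned on carrying the mutant allele there.
    """
    L = len(positions_bp)
    d_morgans = np.diff(positions_bp) / 1e6 * cm_per_mb / 100.0
    r = haldane_r(d_morgans)
    alleles = np.empty((n_gametes, L), dtype=np.int8)
    if anchor_idx is None:
        alleles[:, 0] = rng.integers(0, 2, n_gametes)
        start = 0
    else:
        alleles[:, anchor_idx] = 1
        start = anchor_idx
        for j in range(start - 1, -1, -1):
            flip = rng.random(n_gametes) < r[j]
            alleles[:, j] = np.where(flip, 1 - alleles[:, j + 1], alleles[:, j + 1])
    for j in range(start, L - 1):
        flip = rng.random(n_gametes) < r[j]
        alleles[:, j + 1] = np.where(flip, 1 - alleles[:, j], alleles[:, j])
    return alleles


_CODES = np.array(["B", "H", "A"])  # index = number of mutant-parent alleles


def simulate_f2(spec: F2SimSpec, seed: int | None = None) -> F2Scenario:
    """Simulate an F2 population; each plant is two independent gametes."""
    return _simulate_f2_core(spec, seed, conditioned=False, n_plants=spec.n_plants)


def simulate_mutant_class(spec: F2SimSpec, n_mutants: int, seed: int | None = None) -> F2Scenario:
    """Simulate exactly ``n_mutants`` phenotypically mutant F2 plants.

    Equivalent to drawing F2 plants and keeping mutants: both gametes are
    conditioned on carrying the mutant-parent allele at the causal locus.
    """
    return _simulate_f2_core(spec, seed, conditioned=True, n_plants=n_mutants)


def _simulate_f2_core(spec: F2SimSpec, seed, conditioned: bool, n_plants: int) -> F2Scenario:
    rng = _rng(spec.seed if seed is None else seed, "f2")
    markers = spec.marker_map.sort_values(["chrom", "pos"]).reset_index(drop=True)
    n_gametes = 2 * n_plants
    geno = pd.DataFrame(index=pd.RangeIndex(n_plants, name="plant"), columns=markers["marker_id"], dtype=object)
    causal_dosage = np.zeros(n_plants, dtype=np.int8)

    for chrom, group in markers.groupby("chrom", sort=True):
        positions = group["pos"].to_numpy(float)
        ids = list(group["marker_id"])
        anchor = None
        if chrom == spec.causal_chrom:
            positions = np.append(positions, float(spec.causal_pos))
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            anchor = int(np.where(order == len(ids))[0][0])
        gametes = _chain_gametes(
            rng, positions, spec.cm_per_mb, n_gametes,
            anchor_idx=anchor if conditioned else None,
        )
        g1, g2 = gametes[:n_plants], gametes[n_plants:]
        dosage = g1 + g2
        if chrom == spec.causal_chrom:
            causal_dosage = dosage[:, anchor]
            dosage = np.delete(dosage, anchor, axis=1)
        for k, marker_id in enumerate(ids):
            geno[marker_id] = _CODES[dosage[:, k]]

    if conditioned:
        causal_dosage = np.full(n_plants, 2, dtype=np.int8)
    phenotypes = pd.Series(
        np.where(causal_dosage == 2, "mutant", "wild-type"),
        index=geno.index, name="phenotype",
    )
    if spec.missing_rate > 0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno = geno.mask(mask)
    return F2Scenario(genotypes=geno, phenotypes=phenotypes, marker_map=markers, spec=spec)


# ---------------------------------------------------------------------------
# deletion injection
# ---------------------------------------------------------------------------

def _footprint(markers: pd.DataFrame) -> pd.DataFrame:
    out = markers.copy()
    if "footprint_start" not in out.columns:
        out["footprint_start"] = out["pos"]
        out["footprint_end"] = out["pos"]
    return out


def inject_deletion(
    scenario: PanelScenario | F2Scenario,
    chrom: str,
    start: int,
    end: int,
    carrier: str | None = None,
):
    """Make markers whose primer footprint lies inside [start, end] fail in carriers.

    For a cultivar panel, ``carrier`` names the cultivar holding the
    deletion (default: the second, alternate-parent cultivar); its cells at
    covered markers become missing.  For an F2 scenario the deletion rides
    the mutant-parent chromosome: plants homozygous for it (code A) at a
    covered marker amplify nothing and become missing.  An empty region
    (start > end) leaves the scenario unchanged.

    Returns ``(modified_scenario, failed_marker_ids)``.
    """
    if start > end:
        return scenario, []
    markers = _footprint(scenario.markers if isinstance(scenario, PanelScenario) else scenario.marker_map)
    chrom_col = markers["chrom"] if "chrom" in markers.columns else pd.Series(chrom, index=markers.index)
    covered = (
        (chrom_col == chrom)
        & (markers["footprint_start"] >= start)
        & (markers["footprint_end"] <= end)
    )
    failed = list(markers.loc[covered, "marker_id"])

    if isinstance(scenario, PanelScenario):
        genotypes = scenario.genotypes.copy()
        carrier = carrier or genotypes.columns[1]
        genotypes.loc[genotypes.index.isin(failed), carrier] = np.nan
        return replace(scenario, genotypes=genotypes), failed
    genotypes = scenario.genotypes.copy()
    for marker_id in failed:
        col = genotypes[marker_id]
        genotypes.loc[col == "A", marker_id] = np.nan
    return replace(scenario, genotypes=genotypes), failed
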