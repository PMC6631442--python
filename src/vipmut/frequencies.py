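"""Motif counting and the normalized-SBS-frequency statistics.

The central quantity is the normalized SBS frequency of a motif m in a
gene region:

    nu(m) = (c_sbs(m) / total_sbs) / (c_region(m) / total_region)

i.e. the motif's share among observed substitutions divided by its share
among all positions of the region.  nu = 1 means "mutated exactly as
often as expected from sequence composition".  Motifs are read on the
transcript sense strand for both numerator and denominator, with the
substituted base at the pattern's X position (XN, NXN, NNXNN, ...).

Also here: the transition/transversion ratio R and the pathogenicity
contrast delta-nu = nu_pathogenic - nu_benign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _encoding as enc
from .gene_context import (
    AmbiguousMotifError,
    GeneModel,
    GenomeSequence,
    SBSRecord,
    SiteContext,
    SUPPORTED_PATTERNS,
    motif_at,
)
from .vip_tables import BaseVIPTable, delta_vip

__all__ = [
    "MotifSpec",
    "RegionMotifCounts",
    "SBSMotifCounts",
    "NormalizedFrequencyTable",
    "TsTvResult",
    "DeltaNuTable",
    "count_region_motifs",
    "count_sbs_motifs",
    "normalized_frequency",
    "ts_tv",
    "delta_nu",
    "per_substitution_delta_nu",
    "SUBSTITUTION_TYPES",
]

#: analysis regions; "utr" pools utr5 and utr3 site labels
ANALYSIS_REGIONS = ("exon", "intron", "utr")

_REGION_LABELS = {
    "exon": ("exon",),
    "intron": ("intron",),
    "utr": ("utr5", "utr3"),
    "utr5": ("utr5",),
    "utr3": ("utr3",),
}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SUBSTITUTION_TYPES = tuple(
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
)  # 12 ordered ref->alt types


@dataclass(frozen=True)
class MotifSpec:
    """A motif pattern such as NXN: length and position of the mutated base."""

    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in SUPPORTED_PATTERNS:
            raise ValueError(
                f"pattern {self.pattern!r} not in supported set {SUPPORTED_PATTERNS}"
            )

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def x_index(self) -> int:
        return self.pattern.index("X")


@dataclass
class RegionMotifCounts:
    """Motif occurrence counts over all positions of one gene region."""

    region: str
    spec: MotifSpec
    counts_by_code: np.ndarray  # length 4**k

    @property
    def total(self) -> int:
        return int(self.counts_by_code.sum())

    def as_dict(self) -> dict[str, int]:
        k = self.spec.k
        return {
            enc.code_to_motif(c, k): int(n)
            for c, n in enumerate(self.counts_by_code)
            if n > 0
        }

    def count(self, motif: str) -> int:
        return int(self.counts_by_code[enc.motif_to_code(motif)])

    def frequency(self, motif: str) -> float:
        return self.count(motif) / self.total


@dataclass
class SBSMotifCounts:
    """Motif counts among SBS records matching a region and filter set."""

    region: str
    spec: MotifSpec
    counts_by_code: np.ndarray
    filters: str = ""  # filter descriptor, recorded verbatim in outputs
    n_skipped: int = 0  # records without a usable motif (N or short flank)

    total = RegionMotifCounts.total
    as_dict = RegionMotifCounts.as_dict
    count = RegionMotifCounts.count


def _region_positions(model: GeneModel, region: str) -> np.ndarray:
    segs = []
    for label in _REGION_LABELS[region]:
        segs.extend(model.region_segments(label))
    if not segs:
        return np.empty(0, dtype=np.int64)
    return np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in segs])


def count_region_motifs(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    region: str,
    spec: MotifSpec,
) -> RegionMotifCounts:
    """Count sense-strand motifs over every position of a region.

    Each position of the region in each transcript contributes the motif
    whose X sits on that position; flanking bases may extend past region
    (or transcript) boundaries into contiguous genomic sequence.  Motifs
    touching an N or running off a contig end are skipped.
    """
    if region not in _REGION_LABELS:
        raise ValueError(f"unknown region {region!r}")
    k, x = spec.k, spec.x_index
    counts = np.zeros(4**k, dtype=np.int64)
    total_positions = 0
    encoded: dict[str, np.ndarray] = {}
    for model in models:
        pos = _region_positions(model, region)
        if pos.size == 0:
            continue
        total_positions += pos.size
        if model.chrom not in encoded:
            encoded[model.chrom] = enc.encode(genome.seqs[model.chrom])
        codes = encoded[model.chrom]
        packed, valid = enc.motif_codes_at(codes, pos, k, x, model.strand)
        counts += np.bincount(packed[valid], minlength=4**k)
    if total_positions == 0:
        raise ValueError(f"region {region!r} is empty in the supplied models")
    return RegionMotifCounts(region=region, spec=spec, counts_by_code=counts)


# --- SBS-side filters -------------------------------------------------------


def _clinical_group(record: SBSRecord) -> str | None:
    if record.clinical in ("pathogenic", "likely_pathogenic"):
        return "pathogenic"
    if record.clinical in ("benign", "likely_benign"):
        return "benign"
    return None


def _record_matches(
    record: SBSRecord,
    region: str,
    clinical_group: str | None,
    substitution_class: str | None,
    wild_type: str | None,
    effect: str | None,
) -> bool:
    if record.region not in _REGION_LABELS[region]:
        return False
    if clinical_group is not None and _clinical_group(record) != clinical_group:
        return False
    if substitution_class is not None:
        is_ts = record.is_transition
        if substitution_class == "transition" and not is_ts:
            return False
        if substitution_class == "transversion" and is_ts:
            return False
    if wild_type is not None and record.ref != wild_type:
        return False
    if effect is not None and record.effect != effect:
        return False
    return True


def count_sbs_motifs(
    records: Sequence[SBSRecord],
    contexts: Sequence[SiteContext],
    region: str,
    spec: MotifSpec,
    clinical_group: str | None = None,
    substitution_class: str | None = None,
    wild_type: str | None = None,
    effect: str | None = None,
) -> SBSMotifCounts:
    """Count motifs among records matching a region and optional filters.

    Filters: clinical_group in {pathogenic, benign} (pooling the 'likely'
    annotations), substitution_class in {transition, transversion},
    wild_type base, effect in {missense, synonymous, nonsense, noncoding}.
    """
    k = spec.k
    counts = np.zeros(4**k, dtype=np.int64)
    skipped = 0
    for rec, ctx in zip(records, contexts):
        if not _record_matches(rec, region, clinical_group, substitution_class, wild_type, effect):
            continue
        try:
            motif, _ = motif_at(ctx, spec.pattern)
        except (AmbiguousMotifError, ValueError):
            skipped += 1
            continue
        counts[enc.motif_to_code(motif)] += 1
    desc = ";".join(
        f"{name}={val}"
        for name, val in [
            ("clinical", clinical_group),
            ("class", substitution_class),
            ("wild_type", wild_type),
            ("effect", effect),
        ]
        if val is not None
    )
    return SBSMotifCounts(
        region=region, spec=spec, counts_by_code=counts, filters=desc, n_skipped=skipped
    )


@dataclass
class NormalizedFrequencyTable:
    """Per-motif normalized SBS frequencies for one (region, pattern).

    ``omitted`` lists motifs observed in the SBS set but absent from the
    region background (no defined ratio); motifs with background support
    but zero SBS count are kept at ratio 0.
    """

    region: str
    spec: MotifSpec
    ratios: dict[str, float]
    sbs_total: int
    region_total: int
    omitted: list[str] = field(default_factory=list)
    filters: str = ""

    def weighted_mean(self, region_counts: "RegionMotifCounts") -> float:
        """Mean ratio weighted by region motif frequencies (1 by identity)."""
        w = sum(region_counts.frequency(m) for m in self.ratios)
        return sum(region_counts.frequency(m) * r for m, r in self.ratios.items()) / w


def normalized_frequency(
    sbs_counts: SBSMotifCounts, region_counts: RegionMotifCounts
) -> NormalizedFrequencyTable:
    """Ratio of SBS motif frequency to region background motif frequency."""
    if sbs_counts.spec != region_counts.spec:
        raise ValueError("pattern mismatch between SBS and region counts")
    total_sbs = sbs_counts.total
    total_reg = region_counts.total
    if total_sbs == 0:
        raise ValueError("no SBS motifs counted (empty numerator)")
    if total_reg == 0:
        raise ValueError("empty region background")
    k = sbs_counts.spec.k
    ratios: dict[str, float] = {}
    omitted: list[str] = []
    c_sbs = sbs_counts.counts_by_code
    c_reg = region_counts.counts_by_code
    for code in range(4**k):
        if c_reg[code] == 0:
            if c_sbs[code] > 0:
                omitted.append(enc.code_to_motif(code, k))
            continue
        if c_sbs[code] == 0:
            ratios[enc.code_to_motif(code, k)] = 0.0
        else:
            ratios[enc.code_to_motif(code, k)] = (c_sbs[code] / total_sbs) / (
                c_reg[code] / total_reg
            )
    return NormalizedFrequencyTable(
        region=sbs_counts.region,
        spec=sbs_counts.spec,
        ratios=ratios,
        sbs_total=total_sbs,
        region_total=total_reg,
        omitted=omitted,
        filters=sbs_counts.filters,
    )


@dataclass
class TsTvResult:
    """Transition and transversion counts and their ratio R."""

    n_transitions: int
    n_transversions: int

    @property
    def ratio(self) -> float:
        if self.n_transversions == 0:
            raise ZeroDivisionError("Ts/Tv undefined: zero transversions")
        return self.n_transitions / self.n_transversions


def ts_tv(records: Sequence[SBSRecord]) -> TsTvResult:
    """Transition/transversion tally (A<->G and C<->T are transitions)."""
    if not records:
        raise ValueError("empty record set")
    n_ts = sum(1 for r in records if r.is_transition)
    return TsTvResult(n_transitions=n_ts, n_transversions=len(records) - n_ts)


@dataclass
class DeltaNuTable:
    """Per-motif pathogenic-minus-benign normalized frequency difference."""

    region: str
    spec: MotifSpec
    values: dict[str, float]
    n_pathogenic: int
    n_benign: int


def delta_nu(
    records: Sequence[SBSRecord],
    contexts: Sequence[SiteContext],
    region_counts: RegionMotifCounts,
    spec: MotifSpec,
    substitution_class: str | None = None,
    effect: str | None = None,
) -> DeltaNuTable:
    """delta-nu(m) = nu_pathogenic(m) - nu_benign(m) for one region/pattern.

    Each nu is a normalized frequency computed within the clinical group
    (pathogenic pools pathogenic + likely_pathogenic, benign pools benign
    + likely_benign); VUS/other records are excluded.
    """
    region = region_counts.region
    groups = {}
    for group in ("pathogenic", "benign"):
        groups[group] = count_sbs_motifs(
            records, contexts, region, spec,
            clinical_group=group,
            substitution_class=substitution_class,
            effect=effect,
        )
    n_path, n_ben = groups["pathogenic"].total, groups["benign"].total
    if n_path == 0 or n_ben == 0:
        raise ValueError(
            f"clinical group empty in region {region!r}: "
            f"pathogenic={n_path}, benign={n_ben}"
        )
    nu = {
        g: normalized_frequency(c, region_counts) for g, c in groups.items()
    }
    motifs = set(nu["pathogenic"].ratios) | set(nu["benign"].ratios)
    values = {
        m: nu["pathogenic"].ratios.get(m, 0.0) - nu["benign"].ratios.get(m, 0.0)
        for m in sorted(motifs)
    }
    return DeltaNuTable(
        region=region, spec=spec, values=values, n_pathogenic=n_path, n_benign=n_ben
    )


def per_substitution_delta_nu(
    records: Sequence[SBSRecord],
    base_region_counts: RegionMotifCounts,
    base_table: BaseVIPTable,
    effect: str | None = None,
):
    """delta-nu and |delta-vIP| for each of the 12 ordered ref->alt types.

    nu of a type within a clinical group is the type's share of the
    group's SBSs divided by the region background frequency of the ref
    base (pattern X counts).  Returns a pandas DataFrame with columns
    ref, alt, nu_pathogenic, nu_benign, delta_nu, abs_delta_vip.
    """
    import pandas as pd

    if base_region_counts.spec.k != 1:
        raise ValueError("base_region_counts must use the single-base pattern X")
    region = base_region_counts.region
    by_group: dict[str, dict[tuple[str, str], int]] = {"pathogenic": {}, "benign": {}}
    totals = {"pathogenic": 0, "benign": 0}
    for rec in records:
        if rec.region not in _REGION_LABELS[region]:
            continue
        if effect is not None and rec.effect != effect:
            continue
        g = _clinical_group(rec)
        if g is None:
            continue
        by_group[g][(rec.ref, rec.alt)] = by_group[g].get((rec.ref, rec.alt), 0) + 1
        totals[g] += 1
    if totals["pathogenic"] == 0 or totals["benign"] == 0:
        raise ValueError(
            f"clinical group empty in region {region!r}: "
            f"pathogenic={totals['pathogenic']}, benign={totals['benign']}"
        )
    rows = []
    for ref, alt in SUBSTITUTION_TYPES:
        f_ref = base_region_counts.frequency(ref)
        nu = {}
        for g in ("pathogenic", "benign"):
            share = by_group[g].get((ref, alt), 0) / totals[g]
            nu[g] = share / f_ref if f_ref > 0 else np.nan
        rows.append(
            dict(
                ref=ref,
                alt=alt,
                nu_pathogenic=nu["pathogenic"],
                nu_benign=nu["benign"],
                delta_nu=nu["pathogenic"] - nu["benign"],
                abs_delta_vip=delta_vip(base_table, ref, alt, absolute=True),
            )
        )
    return pd.DataFrame(rows)
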