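"""Genome, gene-model and variant parsing; per-site sequence context.

Every single base substitution (SBS) is assigned to one transcript,
classified by gene region (CDS exon, intron, 5'-UTR, 3'-UTR) and, for
exonic sites, by coding effect (synonymous / missense / nonsense), and
given a strand-resolved flanking context: fifteen bases in the 5'
direction and fifteen in the 3' direction on the transcribed strand.

Coordinates are 0-based half-open internally; GFF3/VCF 1-based inputs
are converted on read.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._encoding import revcomp

log = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "SiteContext",
    "RawVariant",
    "SBSRecord",
    "AmbiguousMotifError",
    "read_genome",
    "read_gene_models",
    "read_variants",
    "classify_site",
    "coding_effect",
    "site_context",
    "motif_at",
    "annotate_variants",
    "TranscriptIndex",
]

REGIONS = ("exon", "intron", "utr5", "utr3")
EFFECTS = ("synonymous", "missense", "nonsense", "noncoding")
CLINICAL = ("pathogenic", "likely_pathogenic", "benign", "likely_benign", "vus", "other")

_ALPHABET = set("ACGTN")


class AmbiguousMotifError(ValueError):
    """Raised when a requested motif contains an ambiguous (N) base."""


@dataclass
class GenomeSequence:
    """Uppercase genome sequences keyed by contig name."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("empty genome")
        for name, s in self.seqs.items():
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"contig {name!r} has non-ACGTN characters {sorted(bad)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def base(self, chrom: str, pos: int) -> str:
        s = self.seqs[chrom]
        if not 0 <= pos < len(s):
            raise IndexError(f"position {pos} outside contig {chrom} (len {len(s)})")
        return s[pos]

    def slice(self, chrom: str, start: int, end: int) -> str:
        s = self.seqs[chrom]
        if start < 0 or end > len(s) or start > end:
            raise IndexError(f"[{start},{end}) outside contig {chrom} (len {len(s)})")
        return s[start:end]


def read_genome(fasta_path: str | Path) -> GenomeSequence:
    """Read a FASTA genome; uppercases sequences, rejects U and duplicates."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {fasta_path}")
        s = str(rec.seq).upper()
        if "U" in s:
            raise ValueError(f"contig {rec.id!r} contains U (RNA alphabet)")
        seqs[rec.id] = s
    return GenomeSequence(seqs)


class ModelError(ValueError):
    """A gene model that violates the structural invariants."""


@dataclass
class GeneModel:
    """One transcript: ordered exons plus a CDS span, 0-based half-open.

    Introns and UTRs are derived from the exon/CDS geometry; `utr5` /
    `utr3` follow the transcription direction, so they swap genomic ends
    between + and - strands.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.id}: bad strand {self.strand!r}")
        ex = sorted(tuple(e) for e in self.exons)
        if not ex or any(s >= e for s, e in ex):
            raise ModelError(f"{self.id}: empty or inverted exon")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ModelError(f"{self.id}: overlapping exons")
        self.exons = ex
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise ModelError(f"{self.id}: CDS outside transcript span")
        # CDS boundaries must fall inside exons
        for bound in (self.cds_start, self.cds_end - 1):
            if not any(s <= bound < e for s, e in ex):
                raise ModelError(f"{self.id}: CDS boundary {bound} outside exons")
        if self.cds_len % 3 != 0:
            raise ModelError(f"{self.id}: spliced CDS length {self.cds_len} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def _cds_pieces(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self._cds_pieces())

    def region_segments(self, region: str) -> list[tuple[int, int]]:
        """Genomic intervals making up one region label of this transcript."""
        if region == "intron":
            return self.introns
        if region == "exon":
            return self._cds_pieces()
        left = [
            (max(s, self.start), min(e, self.cds_start))
            for s, e in self.exons
            if s < self.cds_start
        ]
        left = [(s, e) for s, e in left if s < e]
        right = [
            (max(s, self.cds_end), e) for s, e in self.exons if e > self.cds_end
        ]
        right = [(s, e) for s, e in right if s < e]
        if region == "utr5":
            return left if self.strand == "+" else right
        if region == "utr3":
            return right if self.strand == "+" else left
        raise ValueError(f"unknown region {region!r}")

    def classify(self, pos: int) -> str:
        if not self.start <= pos < self.end:
            raise ValueError(f"position {pos} outside transcript {self.id} span")
        for region in REGIONS:
            if any(s <= pos < e for s, e in self.region_segments(region)):
                return region
        raise AssertionError("region labels must partition the span")

    # --- spliced CDS ---------------------------------------------------
    def cds_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.slice(self.chrom, s, e) for s, e in self._cds_pieces()]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def cds_index(self, pos: int) -> int:
        """Index of a genomic CDS position within the spliced, sense CDS."""
        offset = 0
        for s, e in self._cds_pieces():
            if s <= pos < e:
                i = offset + (pos - s)
                return i if self.strand == "+" else self.cds_len - 1 - i
            offset += e - s
        raise ValueError(f"position {pos} not in CDS of {self.id}")


def _models_from_gff3(path: Path) -> Iterable[dict]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for tr in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
        if not cds:
            log.warning("transcript %s has no CDS; skipped", tr.id)
            continue
        yield dict(
            id=tr.id,
            chrom=tr.seqid,
            strand=tr.strand,
            exons=exons,
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
        )


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
]


def _models_from_bed12(path: Path) -> Iterable[dict]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(row.start + st, row.start + st + sz) for st, sz in zip(starts, sizes)]
        yield dict(
            id=str(row.name),
            chrom=str(row.chrom),
            strand=str(row.strand),
            exons=exons,
            cds_start=int(row.thick_start),
            cds_end=int(row.thick_end),
        )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcripts from GFF3 or BED12; invalid models are dropped.

    A model whose CDS falls outside its exons or whose spliced CDS length
    is not a multiple of three is rejected with a warning rather than
    aborting the run.
    """
    path = Path(path)
    maker = _models_from_bed12 if path.suffix.lower() == ".bed" else _models_from_gff3
    models: list[GeneModel] = []
    for kwargs in maker(path):
        try:
            models.append(GeneModel(**kwargs))
        except ModelError as exc:
            warnings.warn(f"gene model rejected: {exc}")
    return models


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class RawVariant:
    """A plus-strand SBS as read from VCF/TSV (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    clinical: str


_CLNSIG_MAP = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "benign": "benign",
    "likely_benign": "likely_benign",
    "uncertain_significance": "vus",
    "vus": "vus",
}


def map_clnsig(raw: str | None) -> str:
    if raw is None:
        return "other"
    key = str(raw).strip().lower().replace(" ", "_")
    return _CLNSIG_MAP.get(key, "other")


def read_variants(path: str | Path) -> list[RawVariant]:
    """Read SBSs from a VCF (INFO/CLNSIG) or a chrom/pos/ref/alt/clnsig TSV.

    Only single-nucleotide substitutions over ACGT are kept; 1-based
    positions become 0-based.  Unknown clinical strings map to 'other'.
    """
    path = Path(path)
    out: list[RawVariant] = []
    if path.suffix.lower() == ".vcf":
        from cyvcf2 import VCF

        for v in VCF(str(path)):
            alts = v.ALT or []
            for alt in alts:
                if len(v.REF) == 1 and len(alt) == 1 and v.REF in "ACGT" and alt in "ACGT":
                    out.append(
                        RawVariant(v.CHROM, v.POS - 1, v.REF, alt, map_clnsig(v.INFO.get("CLNSIG")))
                    )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "clnsig": str})
        required = {"chrom", "pos", "ref", "alt", "clnsig"}
        if not required <= set(df.columns):
            raise ValueError(f"{path} lacks columns {sorted(required - set(df.columns))}")
        for row in df.itertuples(index=False):
            ref, alt = str(row.ref), str(row.alt)
            if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
                out.append(RawVariant(str(row.chrom), int(row.pos) - 1, ref, alt, map_clnsig(row.clnsig)))
    return out


# ---------------------------------------------------------------------------
# classification


def classify_site(model: GeneModel, pos: int) -> str:
    """Region label of a genomic position: exon (CDS), utr5, utr3, or intron."""
    return model.classify(pos)


def coding_effect(
    model: GeneModel,
    genome: GenomeSequence,
    pos: int,
    ref: str,
    alt: str,
    _cds: str | None = None,
) -> str:
    """Effect of a CDS substitution via the standard genetic code.

    ``ref``/``alt`` are sense-strand bases.  The affected codon is taken
    from the spliced CDS so codons spanning splice junctions are handled.
    ``_cds`` lets callers reuse a precomputed spliced CDS sequence.
    """
    cds = _cds if _cds is not None else model.cds_sequence(genome)
    i = model.cds_index(pos)
    if cds[i] != ref:
        raise ValueError(
            f"{model.id}: sense ref {ref} does not match CDS base {cds[i]} at cds index {i}"
        )
    codon_start = 3 * (i // 3)
    codon = cds[codon_start : codon_start + 3]
    if len(codon) != 3:
        raise ValueError(f"{model.id}: incomplete codon at CDS index {i}")
    alt_codon = codon[: i % 3] + alt + codon[i % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


@dataclass
class SiteContext:
    """Strand-resolved context of one site, in transcript orientation.

    ``up_flank`` is the 5' side and ``down_flank`` the 3' side on the
    sense strand; each is 15 bases unless truncated at a contig end.
    """

    chrom: str
    pos: int
    sense_ref: str
    region: str
    up_flank: str
    down_flank: str
    strand: str = "+"
    truncated: bool = False


def site_context(
    genome: GenomeSequence, model: GeneModel, pos: int, flank: int = 15
) -> SiteContext:
    """Extract the sense-strand base and 5'/3' flanks around a position.

    On - strand transcripts both flanks are reverse-complemented and
    swapped so 5'/3' always refer to the transcription direction.  Flanks
    may cross exon/intron boundaries: they are contiguous genomic
    sequence; only the X position determines the region label.
    """
    seq = genome.seqs[model.chrom]
    if not model.start <= pos < model.end:
        raise ValueError(f"position {pos} outside transcript {model.id} span")
    left = seq[max(0, pos - flank) : pos]
    right = seq[pos + 1 : pos + 1 + flank]
    truncated = len(left) < flank or len(right) < flank
    region = model.classify(pos)
    if model.strand == "+":
        return SiteContext(model.chrom, pos, seq[pos], region, left, right, "+", truncated)
    return SiteContext(
        model.chrom, pos, revcomp(seq[pos]), region,
        revcomp(right), revcomp(left), "-", truncated,
    )


SUPPORTED_PATTERNS = (
    "X", "XN", "NX", "XNN", "NNX", "XNNN", "NNNX", "NXN", "NXNN", "NNXNN", "NNXNNN",
)


def motif_at(context: SiteContext, pattern: str) -> tuple[str, int]:
    """Assemble the motif for a pattern like NXN around the context's X.

    Returns (motif, x_index).  Raises AmbiguousMotifError if the motif
    would contain an N, ValueError if the flanks are too short.
    """
    if pattern not in SUPPORTED_PATTERNS:
        raise ValueError(f"unsupported pattern {pattern!r}")
    x = pattern.index("X")
    after = len(pattern) - x - 1
    if len(context.up_flank) < x or len(context.down_flank) < after:
        raise ValueError(
            f"flanks too short for pattern {pattern} at {context.chrom}:{context.pos}"
        )
    up = context.up_flank[len(context.up_flank) - x :] if x else ""
    motif = up + context.sense_ref + context.down_flank[:after]
    if "N" in motif:
        raise AmbiguousMotifError(f"ambiguous base in motif {motif!r}")
    return motif, x


# ---------------------------------------------------------------------------
# transcript assignment and record annotation


@dataclass(frozen=True)
class SBSRecord:
    """One annotated substitution, ref/alt on the transcript sense strand."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region: str
    effect: str
    clinical: str
    transcript_id: str

    @property
    def is_transition(self) -> bool:
        return {self.ref, self.alt} in ({"A", "G"}, {"C", "T"})


class TranscriptIndex:
    """Maps positions to one transcript: longest CDS, then lexicographic id."""

    def __init__(self, models: Sequence[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        for m in models:
            self.trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m)

    def assign(self, chrom: str, pos: int) -> GeneModel | None:
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return None
        return min(hits, key=lambda m: (-m.cds_len, m.id))


def annotate_variants(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    raws: Sequence[RawVariant],
    flank: int = 15,
) -> tuple[list[SBSRecord], list[SiteContext], Counter]:
    """Assign, strand-resolve and classify raw variants.

    Returns annotated records, their contexts (parallel lists) and a
    counter of skipped records by reason (outside any transcript, ref
    mismatch with the genome).
    """
    index = TranscriptIndex(models)
    records: list[SBSRecord] = []
    contexts: list[SiteContext] = []
    skipped: Counter = Counter()
    cds_cache: dict[str, str] = {}
    for rv in raws:
        model = index.assign(rv.chrom, rv.pos)
        if model is None:
            skipped["no_transcript"] += 1
            continue
        plus_ref = genome.base(rv.chrom, rv.pos)
        if plus_ref != rv.ref:
            skipped["ref_mismatch"] += 1
            log.warning("ref mismatch at %s:%d (%s vs genome %s); dropped",
                        rv.chrom, rv.pos, rv.ref, plus_ref)
            continue
        ctx = site_context(genome, model, rv.pos, flank=flank)
        if model.strand == "+":
            ref, alt = rv.ref, rv.alt
        else:
            ref, alt = revcomp(rv.ref), revcomp(rv.alt)
        region = ctx.region
        if region == "exon":
            if model.id not in cds_cache:
                cds_cache[model.id] = model.cds_sequence(genome)
            effect = coding_effect(model, genome, rv.pos, ref, alt, _cds=cds_cache[model.id])
        else:
            effect = "noncoding"
        records.append(
            SBSRecord(rv.chrom, rv.pos, ref, alt, region, effect, rv.clinical, model.id)
        )
        contexts.append(ctx)
    return records, contexts, skipped
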