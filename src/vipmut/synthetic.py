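"""Synthetic genomes, gene models, vIP tables and SBS sets.

The generator emulates a dbSNP/ClinVar-like substitution catalogue whose
statistical structure matches the assumptions of the analysis:

* a random i.i.d. genome at a configurable GC content carrying gene
  models with alternating exon/intron structure, in-frame CDS and UTRs;
* a motif vIP table built from the additive single-base means with a
  fixed bonus (lowering) per GpG dinucleotide step plus small seeded
  noise, so that G-runs (GGG, GGGG) are guaranteed minimum-vIP motifs
  of their length;
* substitution sites sampled with probability proportional to
  exp(-beta * vIP(rate motif)), so low-vIP contexts mutate more, with a
  transition bias kappa; roughly three quarters of substitutions land
  in (CDS) exons, the rest in introns and UTRs, and about one third of
  records carry a clinical label, assigned pathogenic with probability
  logistic(alpha0 + alpha1*|dvIP| + alpha2*(mean base vIP - motif vIP)).

All randomness flows through one numpy Generator derived from the
config seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _encoding as enc
from .frequencies import MotifSpec, _region_positions
from .gene_context import GeneModel, GenomeSequence, RawVariant
from .vip_tables import StackVIPTable, builtin_base_vips

__all__ = [
    "SynthConfig",
    "synth_genome",
    "synth_vip_table",
    "synth_sbs",
    "ground_truth",
    "write_fasta",
    "write_gff3",
    "write_variants_tsv",
    "write_vcf",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of the synthetic study.

    Defaults reproduce the scale and composition of the real catalogue
    the analysis targets: ~75% of substitutions in exons, introns and
    UTRs splitting the rest roughly 2:3 (UTR mass itself split ~8:30
    between 5' and 3'), one third of records clinically labelled, and a
    transition bias kappa=4 giving a transition/transversion ratio of 2.
    beta (1/eV) couples a motif's vIP to its log substitution rate;
    beta=0.5 with k=3 produces a clearly negative vIP-frequency
    correlation at the default sample size.
    """

    seed: int = 0
    n_genes: int = 80
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (120, 400)
    intron_len: tuple[int, int] = (800, 6000)
    utr5_len: tuple[int, int] = (60, 200)
    utr3_len: tuple[int, int] = (150, 500)
    intergenic_len: tuple[int, int] = (300, 1500)
    gc_content: float = 0.45
    k: int = 3
    rate_pattern: str | None = None  # None -> X centered in a k-mer
    beta: float = 0.5  # 1/eV
    n_sbs: int = 50_000
    ts_bias: float = 4.0  # kappa: transition weight vs 1 per transversion
    label_fraction: float = 1.0 / 3.0
    alpha0: float = 0.0
    alpha1: float = 2.0  # 1/eV, on |dvIP| of the base change
    alpha2: float = 2.0  # 1/eV, on (mean base vIP - motif vIP)
    region_mix: tuple[float, float, float, float] = (0.75, 0.10, 0.03, 0.12)
    # (exon, intron, utr5, utr3) shares of sampled substitutions
    gg_bonus: float = 0.15  # eV lowering per GpG step in the vIP table
    vip_noise_sd: float = 0.02  # eV

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.n_sbs < 1:
            raise ValueError("n_sbs must be >= 1")
        if self.ts_bias <= 0:
            raise ValueError("ts_bias must be > 0")
        if abs(sum(self.region_mix) - 1.0) > 1e-9:
            raise ValueError("region_mix must sum to 1")

    def pattern(self) -> str:
        if self.rate_pattern is not None:
            return self.rate_pattern
        x = (self.k - 1) // 2
        return "N" * x + "X" + "N" * (self.k - 1 - x)


def _rng(config: SynthConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _rand_len(rng, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def synth_genome(config: SynthConfig) -> tuple[GenomeSequence, list[GeneModel]]:
    """One contig of i.i.d. bases carrying alternating-strand gene models.

    Each gene is utr5-exon [intron exon]*-utr3 with the UTRs inside the
    terminal exons and a CDS length trimmed to a multiple of three.
    """
    rng = _rng(config, salt=1)
    p_gc = config.gc_content
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])

    models: list[GeneModel] = []
    cursor = 0
    pieces: list[tuple[int, int]] = []  # (start, end) exon spans per gene, flattened
    gene_specs = []
    for g in range(config.n_genes):
        cursor += _rand_len(rng, config.intergenic_len)
        strand = "+" if g % 2 == 0 else "-"
        n_ex = _rand_len(rng, config.exons_per_gene)
        utr5 = _rand_len(rng, config.utr5_len)
        utr3 = _rand_len(rng, config.utr3_len)
        exon_lens = [_rand_len(rng, config.exon_len) for _ in range(n_ex)]
        # terminal exons must host their UTR plus at least one codon; the
        # 5' UTR sits at the genomic left end on + genes, right end on -
        left_utr, right_utr = (utr5, utr3) if strand == "+" else (utr3, utr5)
        exon_lens[0] = max(exon_lens[0], left_utr + 3)
        exon_lens[-1] = max(exon_lens[-1], right_utr + 3)
        exons = []
        start = cursor
        for i, L in enumerate(exon_lens):
            exons.append((cursor, cursor + L))
            cursor += L
            if i < n_ex - 1:
                cursor += _rand_len(rng, config.intron_len)
        total_exonic = sum(exon_lens)
        if strand == "+":
            cds_start = exons[0][0] + utr5
            cds_len = total_exonic - utr5 - utr3
            cds_len -= cds_len % 3
            if cds_len < 3:
                raise ValueError("gene too short for one codon; widen exon_len")
            # locate cds_end in genomic coordinates
            cds_end = _advance(exons, cds_start, cds_len)
        else:
            cds_end_rev = exons[-1][1] - utr5  # 5' UTR sits at the genomic right end
            cds_len = total_exonic - utr5 - utr3
            cds_len -= cds_len % 3
            if cds_len < 3:
                raise ValueError("gene too short for one codon; widen exon_len")
            cds_start = _retreat(exons, cds_end_rev, cds_len)
            cds_end = cds_end_rev
        models.append(
            GeneModel(
                id=f"g{g:04d}", chrom="chrS", strand=strand,
                exons=exons, cds_start=cds_start, cds_end=cds_end,
            )
        )
    cursor += _rand_len(rng, config.intergenic_len)
    length = cursor
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return GenomeSequence({"chrS": seq}), models


def _advance(exons, start: int, n: int) -> int:
    """Genomic end of a spliced run of n exonic bases starting at start."""
    remaining = n
    for s, e in exons:
        if e <= start:
            continue
        s2 = max(s, start)
        take = min(e - s2, remaining)
        remaining -= take
        if remaining == 0:
            return s2 + take
    raise ValueError("CDS length exceeds exonic space")


def _retreat(exons, end: int, n: int) -> int:
    """Genomic start of a spliced run of n exonic bases ending at end."""
    remaining = n
    for s, e in reversed(exons):
        if s >= end:
            continue
        e2 = min(e, end)
        take = min(e2 - s, remaining)
        remaining -= take
        if remaining == 0:
            return e2 - take
    raise ValueError("CDS length exceeds exonic space")


def synth_vip_table(config: SynthConfig, max_len: int = 4) -> StackVIPTable:
    """Additive-mean vIPs lowered per GpG step, plus small seeded noise.

    Single bases keep the experimental values exactly.  The GpG bonus
    guarantees that G-runs are the minimum-vIP motifs of their length,
    mirroring the expected ordering (GGG lowest among triplets).
    """
    rng = _rng(config, salt=2)
    base = builtin_base_vips()
    arr = base.as_array()
    values: dict[str, float] = {b: base.vip(b) for b in enc.BASES}
    for k in range(2, max_len + 1):
        for code in range(4**k):
            motif = enc.code_to_motif(code, k)
            mean = float(np.mean([base.vip(b) for b in motif]))
            n_gg = sum(1 for i in range(k - 1) if motif[i : i + 2] == "GG")
            noise = float(rng.normal(0.0, config.vip_noise_sd))
            values[motif] = mean - config.gg_bonus * n_gg + noise
        # construction guarantee: the G-run is the strict minimum
        grun = "G" * k
        others = min(v for m, v in values.items() if len(m) == k and m != grun)
        assert values[grun] < others, "GpG bonus too small relative to noise"
    return StackVIPTable(
        values=values,
        source_label=f"synthetic additive-GpG table (seed={config.seed})",
        complete_lengths=frozenset(range(1, max_len + 1)),
    )


# ---------------------------------------------------------------------------
# SBS sampling


_REGION_NAMES = ("exon", "intron", "utr5", "utr3")


def _site_weights(
    codes: np.ndarray,
    positions: np.ndarray,
    strand: str,
    spec: MotifSpec,
    vip_by_code: np.ndarray,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    packed, valid = enc.motif_codes_at(codes, positions, spec.k, spec.x_index, strand)
    vips = np.where(valid, vip_by_code[np.where(valid, packed, 0)], np.nan)
    w = np.exp(-beta * (vips - np.nanmean(vips)))
    w[~valid] = 0.0
    return w, vips


def synth_sbs(
    config: SynthConfig,
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    vip_table: StackVIPTable,
) -> tuple[list[RawVariant], dict]:
    """Sample SBSs with vIP-tilted site probabilities and clinical labels.

    Sites are drawn without replacement (one substitution per site)
    within each region, region totals following ``region_mix``.  Returns
    plus-strand RawVariants plus the ground-truth parameter sidecar.
    """
    rng = _rng(config, salt=3)
    spec = MotifSpec(config.pattern())
    vip_by_code = vip_table.as_array(spec.k)
    if np.isnan(vip_by_code).any():
        raise ValueError(f"vIP table incomplete at length {spec.k}")
    base = builtin_base_vips()
    base_arr = base.as_array()
    mean_base_vip = float(base_arr.mean())

    codes = enc.encode(genome.seqs["chrS"])
    # collect (position, strand) per region over all models
    buckets: dict[str, list[tuple[np.ndarray, str]]] = {r: [] for r in _REGION_NAMES}
    for m in models:
        for region in _REGION_NAMES:
            pos = _region_positions(m, region)
            if pos.size:
                buckets[region].append((pos, m.strand))

    n_per_region = rng.multinomial(config.n_sbs, np.asarray(config.region_mix))
    out_pos: list[np.ndarray] = []
    out_vip: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    for region, n_draw in zip(_REGION_NAMES, n_per_region):
        if n_draw == 0:
            continue
        if not buckets[region]:
            raise ValueError(f"no eligible sites in region {region!r}")
        pos_all, w_all, vip_all, strand_all = [], [], [], []
        for pos, strand in buckets[region]:
            w, vips = _site_weights(codes, pos, strand, spec, vip_by_code, config.beta)
            pos_all.append(pos)
            w_all.append(w)
            vip_all.append(vips)
            strand_all.append(np.full(pos.size, 1 if strand == "+" else -1, dtype=np.int8))
        pos_all = np.concatenate(pos_all)
        w_all = np.concatenate(w_all)
        vip_all = np.concatenate(vip_all)
        strand_all = np.concatenate(strand_all)
        eligible = w_all > 0
        if eligible.sum() < n_draw:
            raise ValueError(
                f"region {region!r} has {int(eligible.sum())} eligible sites, "
                f"need {int(n_draw)}"
            )
        # weighted sampling without replacement: Gumbel top-k on log-weights
        keys = np.full(pos_all.size, -np.inf)
        g = rng.gumbel(size=int(eligible.sum()))
        keys[eligible] = np.log(w_all[eligible]) + g
        take = np.argpartition(-keys, n_draw - 1)[:n_draw]
        out_pos.append(pos_all[take])
        out_vip.append(vip_all[take])
        out_strand.append(strand_all[take])

    pos = np.concatenate(out_pos)
    site_vip = np.concatenate(out_vip)
    strands = np.concatenate(out_strand)
    order = np.argsort(pos, kind="stable")
    pos, site_vip, strands = pos[order], site_vip[order], strands[order]

    # alt base: transition with weight kappa against 1 per transversion
    ref_codes = codes[pos]
    transition_of = np.array([2, 3, 0, 1])  # A<->G, C<->T in code space
    p_ts = config.ts_bias / (config.ts_bias + 2.0)
    u = rng.random(pos.size)
    is_ts = u < p_ts
    alt_codes = np.empty_like(ref_codes)
    alt_codes[is_ts] = transition_of[ref_codes[is_ts]]
    # transversion: pick one of the two non-ref, non-transition bases
    tv_choice = rng.integers(0, 2, size=pos.size)
    for code in range(4):
        mask = (~is_ts) & (ref_codes == code)
        options = [b for b in range(4) if b != code and b != transition_of[code]]
        alt_codes[mask] = np.where(tv_choice[mask] == 0, options[0], options[1])

    # clinical labels use the sense-strand base change: complement the
    # plus-strand codes on - strand genes before taking |dvIP|
    sense_ref = np.where(strands > 0, ref_codes, 3 - ref_codes)
    sense_alt = np.where(strands > 0, alt_codes, 3 - alt_codes)
    abs_dvip = np.abs(base_arr[sense_alt] - base_arr[sense_ref])
    labelled = rng.random(pos.size) < config.label_fraction
    logit = (
        config.alpha0
        + config.alpha1 * abs_dvip
        + config.alpha2 * (mean_base_vip - site_vip)
    )
    p_path = 1.0 / (1.0 + np.exp(-logit))
    pathogenic = rng.random(pos.size) < p_path

    variants = []
    for i in range(pos.size):
        if labelled[i]:
            clin = "pathogenic" if pathogenic[i] else "benign"
        else:
            clin = "vus"
        variants.append(
            RawVariant(
                chrom="chrS",
                pos=int(pos[i]),
                ref=enc.BASES[ref_codes[i]],
                alt=enc.BASES[alt_codes[i]],
                clinical=clin,
            )
        )
    truth = ground_truth(config)
    truth["n_emitted"] = len(variants)
    return variants, truth


def ground_truth(config: SynthConfig) -> dict:
    """All generative parameters, for recovery tests and JSON sidecars."""
    d = asdict(config)
    d["rate_pattern_resolved"] = config.pattern()
    return d


# ---------------------------------------------------------------------------
# writers (plain-text standard formats)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tvipmut\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID=gene_{m.id}\n"
            )
            fh.write(
                f"{m.chrom}\tvipmut\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.id};Parent=gene_{m.id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tvipmut\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.id}\n"
                )
            pieces = m._cds_pieces()
            ordered = pieces if m.strand == "+" else list(reversed(pieces))
            done = 0
            phases = {}
            for s, e in ordered:
                phases[(s, e)] = (3 - done % 3) % 3
                done += e - s
            for s, e in pieces:
                fh.write(
                    f"{m.chrom}\tvipmut\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                    f"{phases[(s, e)]}\tParent={m.id}\n"
                )


_CLIN_OUT = {"pathogenic": "Pathogenic", "benign": "Benign", "vus": "Uncertain_significance"}


def write_variants_tsv(variants: Sequence[RawVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclnsig\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t"
                f"{_CLIN_OUT.get(v.clinical, v.clinical)}\n"
            )


def write_vcf(variants: Sequence[RawVariant], path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##vipmut_seed={seed}\n")
        fh.write('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"CLNSIG={_CLIN_OUT.get(v.clinical, v.clinical)}\n"
            )


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
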