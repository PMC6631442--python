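"""End-to-end orchestration: inputs -> counts -> statistics -> report.

`run` executes the full analysis on files (genome FASTA, gene models,
variant table, vIP table) and writes a report bundle of TSV tables:
normalized frequencies, the correlation/slope matrix per region and
pattern, the 5'-3' asymmetry table, and the pathogenicity correlations
(vIP vs delta-nu per motif, and |dvIP| vs delta-nu over the 12
substitution types).  `analyze` is the in-memory core used by both the
CLI and the acceptance machinery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import frequencies as fq
from . import stats as st
from .gene_context import (
    GeneModel,
    GenomeSequence,
    SBSRecord,
    SiteContext,
    annotate_variants,
    read_gene_models,
    read_genome,
    read_variants,
)
from .vip_tables import (
    StackVIPTable,
    builtin_base_vips,
    load_stack_table,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run", "analyze"]

DEFAULT_PATTERNS = ("XN", "NXN", "NXNN", "NNXNN", "NNXNNN")

#: analysis groups: exonic SBSs are split by coding effect
GROUPS = ("missense", "synonymous", "intron", "utr")

_GROUP_ARGS = {
    "missense": dict(region="exon", effect="missense"),
    "synonymous": dict(region="exon", effect="synonymous"),
    "intron": dict(region="intron"),
    "utr": dict(region="utr"),
}
_GROUP_REGION = {"missense": "exon", "synonymous": "exon", "intron": "intron", "utr": "utr"}


@dataclass
class RunConfig:
    genome: str
    models: str
    variants: str
    vip_table: str
    outdir: str
    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    groups: tuple[str, ...] = GROUPS
    asymmetry_patterns: tuple[str, ...] = ("XN", "NX", "XNN", "NNX", "XNNN", "NNNX")
    flank: int = 15

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    frequencies: pd.DataFrame  # long table of per-motif normalized frequencies
    correlations: pd.DataFrame  # region x pattern x subset matrix
    asymmetry: pd.DataFrame
    ts_tv: pd.DataFrame
    pathogenicity_vip: pd.DataFrame  # vIP vs delta-nu
    pathogenicity_dvip: pd.DataFrame  # |dvIP| vs delta-nu over the 12 types
    runlog: dict


def _freq_tables(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    records: Sequence[SBSRecord],
    contexts: Sequence[SiteContext],
    patterns: Sequence[str],
    groups: Sequence[str],
) -> tuple[dict, dict]:
    """Normalized-frequency tables and region background counts per group/pattern."""
    region_counts: dict[tuple[str, str], fq.RegionMotifCounts] = {}
    tables: dict[tuple[str, str], fq.NormalizedFrequencyTable] = {}
    for pattern in patterns:
        spec = fq.MotifSpec(pattern)
        per_region = {
            region: fq.count_region_motifs(genome, models, region, spec)
            for region in {_GROUP_REGION[g] for g in groups}
        }
        for group in groups:
            rc = per_region[_GROUP_REGION[group]]
            region_counts[(group, pattern)] = rc
            sbs = fq.count_sbs_motifs(records, contexts, spec=spec, **_GROUP_ARGS[group])
            if sbs.total == 0:
                log.warning("no SBSs for group %s pattern %s; table skipped", group, pattern)
                continue
            tables[(group, pattern)] = fq.normalized_frequency(sbs, rc)
    return tables, region_counts


def analyze(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    records: Sequence[SBSRecord],
    contexts: Sequence[SiteContext],
    stack_table: StackVIPTable,
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    groups: Sequence[str] = GROUPS,
    asymmetry_patterns: Sequence[str] = ("XN", "NX", "XNN", "NNX", "XNNN", "NNNX"),
    pathogenicity: bool = True,
) -> ReportBundle:
    """Full in-memory analysis over annotated records."""
    tables, region_counts = _freq_tables(genome, models, records, contexts, patterns, groups)

    freq_rows = []
    for (group, pattern), table in tables.items():
        for motif, ratio in sorted(table.ratios.items()):
            freq_rows.append(
                dict(region=group, pattern=pattern, motif=motif,
                     count=region_counts[(group, pattern)].count(motif),
                     normalized_frequency=ratio)
            )
    corr = st.vip_frequency_analysis(stack_table, tables)

    asym_tables, _ = _freq_tables(genome, models, records, contexts, asymmetry_patterns, groups)
    asym = pd.DataFrame(
        [
            dict(region=a.region, length=a.length, r_forward=a.r_forward,
                 r_reverse=a.r_reverse, diff=a.diff, n=a.n, p=a.p)
            for a in st.asymmetry_analysis(stack_table, asym_tables)
        ]
    )

    tstv_rows = []
    for group in groups:
        sel = [
            r for r in records
            if fq._record_matches(r, _GROUP_ARGS[group]["region"], None, None, None,
                                  _GROUP_ARGS[group].get("effect"))
        ]
        if not sel:
            continue
        res = fq.ts_tv(sel)
        ratio = res.ratio if res.n_transversions else np.nan
        tstv_rows.append(
            dict(region=group, n_transitions=res.n_transitions,
                 n_transversions=res.n_transversions, R=ratio)
        )

    path_vip = pd.DataFrame()
    path_dvip = pd.DataFrame()
    if pathogenicity:
        path_vip = pathogenicity_vip_analysis(stack_table, records, contexts, region_counts,
                                              patterns, groups)
        path_dvip = pathogenicity_dvip_analysis(genome, models, records, groups)

    runlog = dict(
        n_records=len(records),
        groups=list(groups),
        patterns=list(patterns),
        tables={f"{g}/{p}": t.sbs_total for (g, p), t in tables.items()},
    )
    return ReportBundle(
        frequencies=pd.DataFrame(freq_rows),
        correlations=corr,
        asymmetry=asym,
        ts_tv=pd.DataFrame(tstv_rows),
        pathogenicity_vip=path_vip,
        pathogenicity_dvip=path_dvip,
        runlog=runlog,
    )


def pathogenicity_vip_analysis(
    stack_table: StackVIPTable,
    records: Sequence[SBSRecord],
    contexts: Sequence[SiteContext],
    region_counts: Mapping[tuple[str, str], fq.RegionMotifCounts],
    patterns: Sequence[str],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Correlate motif vIP with delta-nu per group/pattern/substitution class."""
    from .vip_tables import motif_vip

    rows = []
    for group in groups:
        for pattern in patterns:
            if (group, pattern) not in region_counts:
                continue
            spec = fq.MotifSpec(pattern)
            for sub_class in (None, "transition", "transversion"):
                row = dict(
                    region=group, pattern=pattern,
                    subset="All" if sub_class is None else sub_class + "s",
                    n=0, r=np.nan, p=np.nan, computable=False,
                )
                try:
                    dn = fq.delta_nu(
                        records, contexts, region_counts[(group, pattern)], spec,
                        substitution_class=sub_class,
                        effect=_GROUP_ARGS[group].get("effect"),
                    )
                except ValueError:
                    rows.append(row)
                    continue
                x = [motif_vip(stack_table, m) for m in dn.values]
                y = list(dn.values.values())
                row["n"] = len(x)
                if len(x) >= 4 and np.ptp(x) > 0 and np.ptp(y) > 0:
                    res = st.pearson(x, y)
                    row.update(r=res.r, p=res.p, computable=True)
                rows.append(row)
    return pd.DataFrame(rows)


def pathogenicity_dvip_analysis(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    records: Sequence[SBSRecord],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Correlate |dvIP| of the base change with delta-nu over the 12 types."""
    base = builtin_base_vips()
    rows = []
    spec1 = fq.MotifSpec("X")
    for group in groups:
        region = _GROUP_REGION[group]
        rc1 = fq.count_region_motifs(genome, models, region, spec1)
        try:
            df = fq.per_substitution_delta_nu(
                records, rc1, base, effect=_GROUP_ARGS[group].get("effect")
            )
        except ValueError:
            rows.append(dict(region=group, n=0, r=np.nan, p=np.nan, computable=False))
            continue
        sub = df.dropna(subset=["delta_nu", "abs_delta_vip"])
        row = dict(region=group, n=len(sub), r=np.nan, p=np.nan, computable=False)
        if len(sub) >= 4 and sub["abs_delta_vip"].nunique() > 1 and sub["delta_nu"].nunique() > 1:
            res = st.pearson(sub["abs_delta_vip"], sub["delta_nu"])
            row.update(r=res.r, p=res.p, computable=True)
        rows.append(row)
    return pd.DataFrame(rows)


_BUNDLE_FILES = {
    "frequencies": "normalized_frequencies.tsv",
    "correlations": "correlations.tsv",
    "asymmetry": "asymmetry.tsv",
    "ts_tv": "ts_tv.tsv",
    "pathogenicity_vip": "pathogenicity_vip.tsv",
    "pathogenicity_dvip": "pathogenicity_dvip.tsv",
}


def write_bundle(bundle: ReportBundle, outdir: str | Path, meta: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BUNDLE_FILES.items():
        df: pd.DataFrame = getattr(bundle, attr)
        df.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
    runlog = dict(bundle.runlog)
    if meta:
        runlog.update(meta)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run(config: RunConfig) -> ReportBundle:
    """Execute the pipeline on files and write the report bundle."""
    genome = read_genome(config.genome)
    models = read_gene_models(config.models)
    raws = read_variants(config.variants)
    records, contexts, skipped = annotate_variants(genome, models, raws, flank=config.flank)
    stack = load_stack_table(config.vip_table)
    bundle = analyze(
        genome, models, records, contexts, stack,
        patterns=config.patterns, groups=config.groups,
        asymmetry_patterns=config.asymmetry_patterns,
    )
    bundle.runlog.update(
        records_in=len(raws),
        records_used=len(records),
        records_skipped=dict(skipped),
        config_hash=config.digest(),
    )
    write_bundle(bundle, config.outdir, meta={"config": config.__dict__})
    return bundle
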