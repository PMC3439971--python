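"""End-to-end orchestration: discover -> quantify -> enrich -> classify ->
fold changes (-> optional Rank Product / regulated-NAT calls), with a
summary report of siRNA-producing pairs by topology and region accounting.

All randomness flows from ``RunConfig.seed`` through named substreams,
and outputs are written with stable ordering and formatting so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .differential_expression import (
    antisense_sirna_presence,
    call_sirna_regulated,
    condition_fold_changes,
    rank_product,
)
from .enrichment_stats import pair_densities, paired_density_test
from .genome_io import Library, load_bed, parse_annotation, validate_library_controls
from .nat_discovery import ExclusionPolicy, apply_exclusions, find_nat_pairs, write_pairs_tsv
from .sirna_profile import build_profile, normalize_per_million, region_accounting, summarize_pair
from .util import pct_half_up, substream

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """All stage inputs and thresholds (defaults are the analysis values)."""

    gff: str = ""
    beds: dict[str, str] = field(default_factory=dict)  # library_id -> BED path
    libraries_tsv: str = ""
    expr_tsv: str | None = None
    outdir: str = "natsirna_out"
    seed: int = 0
    overlap_min: int = 25
    rpm_min: float = 10.0
    cluster_window: int = 10
    cluster_min_reads: int = 6
    max_clusters: int = 10
    frac_min: float = 0.5
    bias_ratio: float = 2.0
    fc_ratio: float = 2.0
    de_fc: float = 1.5
    de_p: float = 0.05
    n_perm: int = 1000
    unique_only: bool = False
    count_copies: bool = False
    excluded_biotypes: list[str] = field(
        default_factory=lambda: ["rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "ta_siRNA", "transposon"]
    )
    retain_pair_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("overlap_min", "rpm_min", "cluster_window", "cluster_min_reads",
                     "max_clusters", "frac_min", "bias_ratio", "fc_ratio", "de_fc", "de_p", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def load_libraries_tsv(path: str | Path) -> dict[str, Library]:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    libs = {}
    for _, row in df.iterrows():
        ctl = row.get("control_id", "")
        libs[str(row["library_id"])] = Library(
            library_id=str(row["library_id"]),
            condition=str(row.get("condition", "")),
            control_id=str(ctl) if isinstance(ctl, str) and ctl else None,
            total_mapped=int(row["total_mapped"]),
        )
    validate_library_controls(libs.values())
    return libs


def topology_report(pairs, excluded, summaries) -> pd.DataFrame:
    """Counts and percentages of siRNA-producing pairs by topology.

    Percentages are 100 x count / stated denominator, rounded half-up to
    one decimal: the >=10-rpm rate over analyzed pairs; the exclusive-OR,
    2x-enriched, and strand-bias rates over the pairs passing 10 rpm.
    """
    by_id = {s.pair_id: s for s in summaries}
    rows = []
    all_pairs = list(pairs) + [p for p, _ in excluded]
    for topo in ("convergent", "divergent", "enclosed", "total"):
        sel = lambda ps: [p for p in ps if topo in ("total", p.topology)]  # noqa: E731
        n_all = len(sel(all_pairs))
        analyzed = sel(pairs)
        n_analyzed = len(analyzed)
        passing = [by_id[p.pair_id] for p in analyzed if by_id[p.pair_id].passes_10rpm]
        n_pass = len(passing)
        n_excl = sum(1 for s in passing if s.exclusive_or)
        n_enr = sum(1 for s in passing if s.or_enriched_2x)
        n_bias = sum(1 for s in passing if s.strand_biased)
        rows.append(
            {
                "topology": topo,
                "all_pairs": n_all,
                "analyzed": n_analyzed,
                "pass_10rpm": n_pass,
                "pass_10rpm_pct": pct_half_up(n_pass, n_analyzed),
                "exclusive_OR": n_excl,
                "exclusive_OR_pct": pct_half_up(n_excl, n_pass),
                "enriched_2x": n_enr,
                "enriched_2x_pct": pct_half_up(n_enr, n_pass),
                "strand_bias": n_bias,
                "strand_bias_pct": pct_half_up(n_bias, n_pass),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage from annotation + mapped reads on disk.

    Writes pairs.tsv, profile.tsv, summaries.tsv, table1.tsv, table2.tsv,
    enrichment.tsv, patterns.tsv, foldchanges.tsv (+ rankprod.tsv and
    regulated.tsv when an expression matrix is supplied) and run_info.txt
    under ``config.outdir``; returns the in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = parse_annotation(config.gff)
    pairs_all = find_nat_pairs(genes, min_overlap=config.overlap_min)
    policy = ExclusionPolicy(
        excluded_biotypes=frozenset(config.excluded_biotypes),
        retain_pair_ids=frozenset(config.retain_pair_ids),
    )
    pairs, excluded = apply_exclusions(pairs_all, policy)
    write_pairs_tsv(pairs, excluded, str(outdir / "pairs.tsv"))

    libraries = load_libraries_tsv(config.libraries_tsv)
    reads = []
    for lib_id, bed_path in sorted(config.beds.items()):
        lib_reads, _ = load_bed(bed_path, library_id=lib_id)
        reads.extend(lib_reads)
        if lib_id not in libraries:
            raise ValueError(f"BED library {lib_id!r} missing from libraries table")

    profile = build_profile(pairs, reads)
    profile = normalize_per_million(profile, libraries)
    profile.sort_values(["pair_id", "library_id", "start", "strand", "sequence"]).to_csv(
        outdir / "profile.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    summaries = [
        summarize_pair(p, profile, rpm_min=config.rpm_min, bias_ratio=config.bias_ratio)
        for p in pairs
    ]
    pd.DataFrame(
        [
            {
                "pair_id": s.pair_id,
                "or_rpm_sum": s.or_rpm_sum,
                "passes_10rpm": s.passes_10rpm,
                "exclusive_or": s.exclusive_or,
                "or_enriched_2x": s.or_enriched_2x,
                "strand_bias_ratio": s.strand_bias_ratio,
                "strand_biased": s.strand_biased,
            }
            for s in summaries
        ]
    ).to_csv(outdir / "summaries.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    table1 = topology_report(pairs, excluded, summaries)
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    table2 = region_accounting(profile)
    table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)

    records = pair_densities(pairs, reads, count_copies=config.count_copies)
    enrichment = None
    if sum(r.testable for r in records) >= 2:
        enrichment = paired_density_test(records)
        pd.DataFrame(
            [
                {
                    "t_stat": enrichment.t_stat,
                    "dof": enrichment.dof,
                    "p_one_tail": enrichment.p_one_tail,
                    "A_o": enrichment.a_o,
                    "A_g": enrichment.a_g,
                    "score": enrichment.score,
                }
            ]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    by_id = {s.pair_id: s for s in summaries}
    patterns = []
    grouped = dict(tuple(profile.groupby("pair_id"))) if len(profile) else {}
    for p in pairs:
        if not by_id[p.pair_id].passes_10rpm or p.pair_id not in grouped:
            continue
        patterns.append(_classify_from_rows(p.pair_id, grouped[p.pair_id], config))
    pd.DataFrame(
        [
            {
                "pair_id": c.pair_id,
                "n_clusters": c.n_clusters,
                "frac_in_clusters": c.frac_in_clusters,
                "label": c.label,
            }
            for c in patterns
        ]
    ).to_csv(outdir / "patterns.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    fc_rows = []
    for p in pairs:
        rows = grouped.get(p.pair_id)
        rpm_by_lib = (
            rows[rows["zone"] == "overlap"].groupby("library_id")["rpm"].sum().to_dict()
            if rows is not None
            else {}
        )
        fc = condition_fold_changes(p.pair_id, rpm_by_lib, libraries)
        fc_rows.append(
            {
                "pair_id": p.pair_id,
                **{f"fc_{c}": v for c, v in sorted(fc.fold_changes.items())},
                "max_abs_fc": fc.max_abs_fc,
                "regulated": fc.regulated,
            }
        )
    pd.DataFrame(fc_rows).to_csv(
        outdir / "foldchanges.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    de_results = None
    calls = None
    if config.expr_tsv:
        matrix = pd.read_csv(config.expr_tsv, sep="\t", index_col=0)
        mutant_cols = sorted(c for c in matrix.columns if c.startswith("mutant_"))
        pairing = [(m, m.replace("mutant_", "control_")) for m in mutant_cols]
        rp_seed = int(substream(config.seed, "rankprod").integers(2**31))
        de_results = rank_product(matrix, pairing, n_perm=config.n_perm, seed=rp_seed)
        de_results.to_csv(outdir / "rankprod.tsv", sep="\t", float_format=FLOAT_FORMAT)
        presence = antisense_sirna_presence(profile, pairs)
        callable_de = de_results[de_results.index.isin(presence.keys())]
        calls = call_sirna_regulated(
            callable_de, presence, fc_min=config.de_fc, p_max=config.de_p
        )
        pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "fc": c.fc,
                    "p": c.p,
                    "up_1p5": c.up_1p5,
                    "sig": c.sig,
                    "opposite_sirna": c.opposite_sirna,
                    "called": c.called,
                }
                for c in calls
            ]
        ).to_csv(outdir / "regulated.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    (outdir / "run_info.txt").write_text(
        "natsirna version: %s\nseed: %d\nthresholds: overlap_min=%d rpm_min=%g "
        "cluster_window=%d cluster_min_reads=%d max_clusters=%d frac_min=%g "
        "bias_ratio=%g fc_ratio=%g de_fc=%g de_p=%g n_perm=%d\n"
        % (
            __version__,
            config.seed,
            config.overlap_min,
            config.rpm_min,
            config.cluster_window,
            config.cluster_min_reads,
            config.max_clusters,
            config.frac_min,
            config.bias_ratio,
            config.fc_ratio,
            config.de_fc,
            config.de_p,
            config.n_perm,
        )
    )
    return {
        "genes": genes,
        "pairs": pairs,
        "excluded": excluded,
        "profile": profile,
        "summaries": summaries,
        "table1": table1,
        "table2": table2,
        "enrichment": enrichment,
        "patterns": patterns,
        "fold_changes": fc_rows,
        "rankprod": de_results,
        "regulated": calls,
    }


def _classify_from_rows(pair_id: str, rows: pd.DataFrame, config: RunConfig):
    from .pattern_classifier import classify_pattern, cluster_reads

    pos_copies = list(zip(rows["start"].tolist(), rows["copies"].tolist()))
    clusters = cluster_reads(pos_copies, window_len=config.cluster_window)
    return classify_pattern(
        clusters,
        int(rows["copies"].sum()),
        pair_id=pair_id,
        max_clusters=config.max_clusters,
        frac_min=config.frac_min,
        min_cluster_reads=config.cluster_min_reads,
    )
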