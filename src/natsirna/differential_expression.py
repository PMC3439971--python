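"""Stress-response fold changes of nat-siRNA abundance and Rank Product
differential expression.

Fold changes compare per-library rpm of a pair's overlap-region siRNAs
between each treatment and its matched control, with a 1-rpm pseudocount,
reported as signed ratios (+r up, -r down, |r| >= 1). Rank Product ranks
genes by fold change within each replicate pair and scores each gene by
the geometric mean of its ranks; significance comes from within-replicate
permutations, which reduce to uniformly random rank matrices and give a
percentage-of-false-prediction (pfp) estimate per the original
convention (expected false positives divided by the number of calls at
that rank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Library
from .util import signed_ratio

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Condition fold changes of siRNA abundance
# ---------------------------------------------------------------------------


@dataclass
class ConditionFoldChange:
    pair_id: str
    fold_changes: dict[str, float] = field(default_factory=dict)  # condition -> signed fc

    @property
    def max_abs_fc(self) -> float:
        if not self.fold_changes:
            return 1.0
        return max(self.fold_changes.values(), key=lambda v: (abs(v), v))

    @property
    def regulated(self) -> bool:
        return abs(self.max_abs_fc) > 2.0


def condition_fold_changes(
    pair_id: str,
    rpm_by_library: Mapping[str, float],
    libraries: Mapping[str, Library],
    pseudocount: float = 1.0,
) -> ConditionFoldChange:
    """Signed per-condition fold change of a pair's siRNA abundance.

    For each treatment library with a control link, the ratio
    (treat + c) / (control + c) is converted to a signed value; the
    maximum-|fc| condition decides the regulated flag (strict |fc| > 2).
    """
    fcs: dict[str, float] = {}
    for lib_id, lib in libraries.items():
        if lib.control_id is None:
            continue
        if lib.control_id not in libraries:
            raise ValueError(f"library {lib_id!r} names missing control {lib.control_id!r}")
        treat = rpm_by_library.get(lib_id, 0.0)
        control = rpm_by_library.get(lib.control_id, 0.0)
        ratio = (treat + pseudocount) / (control + pseudocount)
        fcs[lib.condition or lib_id] = signed_ratio(ratio)
    return ConditionFoldChange(pair_id=pair_id, fold_changes=fcs)


# ---------------------------------------------------------------------------
# Rank Product
# ---------------------------------------------------------------------------


@dataclass
class RankProductResult:
    gene: str
    rp_up: float
    rp_down: float
    pfp_up: float
    pfp_down: float
    p_up: float
    p_down: float
    fc: float  # mean fold change (ratio scale) across replicate pairs


def _null_rp_pool(n_genes: int, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null RP values from uniformly random rank matrices.

    Permuting expression values within each replicate makes each
    replicate's rank column an independent uniform permutation of 1..n,
    so the null RP distribution can be drawn directly.
    """
    logs = np.zeros((n_perm, n_genes))
    for _ in range(k):
        ranks = np.argsort(rng.random((n_perm, n_genes)), axis=1) + 1
        logs += np.log(ranks)
    return np.exp(logs / k).ravel()


def rank_product(
    matrix: pd.DataFrame,
    pairing: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank Product differential expression over paired replicates.

    ``matrix`` holds positive expression values (genes x samples);
    ``pairing`` lists (treatment_sample, control_sample) replicate pairs.
    Up- and down-regulation are scored separately (rank 1 = strongest in
    that direction). Returns one row per gene with RP, permutation p, and
    pfp for both directions, sorted as the input. Deterministic given seed.
    """
    k = len(pairing)
    if k == 0:
        raise ValueError("no replicate pairs defined")
    genes = matrix.index.to_numpy()
    n = len(genes)
    log_fc = np.column_stack(
        [np.log2(matrix[t].to_numpy() / matrix[c].to_numpy()) for t, c in pairing]
    )
    up_ranks = np.column_stack([stats.rankdata(-log_fc[:, j], method="ordinal") for j in range(k)])
    down_ranks = np.column_stack([stats.rankdata(log_fc[:, j], method="ordinal") for j in range(k)])
    rp_up = np.exp(np.log(up_ranks).mean(axis=1))
    rp_down = np.exp(np.log(down_ranks).mean(axis=1))

    rng = np.random.default_rng(seed)
    pool = np.sort(_null_rp_pool(n, k, n_perm, rng))

    def pfp_and_p(rp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = np.searchsorted(pool, rp, side="right").astype(float)
        expected = c / n_perm  # expected false positives at this RP
        order_rank = stats.rankdata(rp, method="max")  # calls at least this extreme
        pfp = expected / order_rank
        p = c / (n_perm * n)
        return pfp, p

    pfp_up, p_up = pfp_and_p(rp_up)
    pfp_down, p_down = pfp_and_p(rp_down)
    mean_fc = np.exp2(log_fc.mean(axis=1))
    return pd.DataFrame(
        {
            "gene": genes,
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
            "p_up": p_up,
            "p_down": p_down,
            "fc": mean_fc,
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# siRNA-regulated NAT caller
# ---------------------------------------------------------------------------


@dataclass
class RegulatedNatCall:
    gene: str
    fc: float
    p: float
    up_1p5: bool
    sig: bool
    opposite_sirna: bool

    @property
    def called(self) -> bool:
        return self.up_1p5 and self.sig and self.opposite_sirna


def antisense_sirna_presence(profile: pd.DataFrame, pairs) -> dict[str, bool]:
    """Per NAT gene: does the pair produce >= 1 siRNA locus antisense to it?

    A locus is antisense to a gene when its strand is opposite the gene's
    and it intersects the gene span (origin_gene in the profile is the
    same-strand gene, so loci originating from the partner qualify when
    they fall inside this gene).
    """
    presence: dict[str, bool] = {}
    by_pair = dict(tuple(profile.groupby("pair_id"))) if len(profile) else {}
    for pair in pairs:
        rows = by_pair.get(pair.pair_id)
        for gene in pair.genes:
            key = gene.gene_id
            presence.setdefault(key, False)
            if rows is None:
                continue
            anti = rows[
                (rows["strand"] != gene.strand)
                & (rows["start"] + rows["length"] > gene.span[0])
                & (rows["start"] < gene.span[1])
            ]
            if len(anti):
                presence[key] = True
    return presence


def call_sirna_regulated(
    de_table: pd.DataFrame,
    antisense_presence: Mapping[str, bool],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    p_column: str = "p_up",
) -> list[RegulatedNatCall]:
    """Call siRNA-regulated NAT transcripts.

    A gene is called when it is up-regulated more than ``fc_min``-fold
    with ``p_column`` (permutation p or pfp; both accepted) below
    ``p_max``, and its pair produces siRNAs on the opposite strand.
    Genes absent from the siRNA profiles are skipped and logged.
    """
    calls: list[RegulatedNatCall] = []
    for gene, row in de_table.iterrows():
        if gene not in antisense_presence:
            log.warning("gene %s has no siRNA profile; not callable", gene)
            continue
        fc = float(row["fc"])
        p = float(row[p_column])
        calls.append(
            RegulatedNatCall(
                gene=str(gene),
                fc=fc,
                p=p,
                up_1p5=fc > fc_min,
                sig=p < p_max,
                opposite_sirna=bool(antisense_presence[str(gene)]),
            )
        )
    return calls
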