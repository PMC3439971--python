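"""AGO pull-down loading of nat-siRNAs.

Identified nat-siRNA sequences are matched exactly (sequence identity,
not position) against each Argonaute immunoprecipitation read set,
normalized to reads-per-million of the AGO library's genome-mapped total,
and expressed as each AGO's percentage of the summed normalized loading.
Size classes default to 20-22 nt (short) and 23-26 nt (long) for AGO
analysis; the profiling long class elsewhere is 23-28 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

AGO_SIZE_CLASSES = {"20-22": (20, 22), "23-26": (23, 26)}


@dataclass
class AgoLibrary:
    ago_id: str
    reads: dict[str, int]  # collapsed sequence -> copies
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped < 0:
            raise ValueError("total_mapped must be >= 0")


@dataclass
class AgoEnrichment:
    ago_id: str
    loaded_unique: int
    loaded_copies: int
    loaded_rpm: float
    pct_of_total: float


def ago_enrichment(
    nat_sirnas: Iterable[str],
    ago_libraries: Sequence[AgoLibrary],
    size_class: tuple[int, int] | str | None = None,
) -> list[AgoEnrichment]:
    """Relative loading of a nat-siRNA set across AGO pull-downs.

    ``size_class`` restricts the nat-siRNA set by length (a (lo, hi)
    tuple or a named class like "20-22"). A sequence present in several
    AGO sets counts in each. Percentages sum to 100 whenever any loading
    is nonzero; an all-zero loading reports 0 percentages with a warning.
    """
    if isinstance(size_class, str):
        size_class = AGO_SIZE_CLASSES[size_class]
    targets = {
        s for s in nat_sirnas if size_class is None or size_class[0] <= len(s) <= size_class[1]
    }
    loaded: list[tuple[str, int, int, float]] = []
    for lib in ago_libraries:
        hits = {s: c for s, c in lib.reads.items() if s in targets}
        copies = sum(hits.values())
        rpm = copies * 1e6 / lib.total_mapped if lib.total_mapped > 0 else 0.0
        loaded.append((lib.ago_id, len(hits), copies, rpm))
    total_rpm = sum(r for *_, r in loaded)
    if total_rpm == 0:
        log.warning("no nat-siRNA loading detected in any AGO library")
    return [
        AgoEnrichment(
            ago_id=ago,
            loaded_unique=uniq,
            loaded_copies=copies,
            loaded_rpm=rpm,
            pct_of_total=(100.0 * rpm / total_rpm) if total_rpm > 0 else 0.0,
        )
        for ago, uniq, copies, rpm in loaded
    ]


def load_collapsed_tsv(path, ago_id: str, total_mapped: int | None = None) -> AgoLibrary:
    """Read a two-column (sequence, copies) TSV as one AGO library.

    When ``total_mapped`` is not given, the summed copies are used as the
    normalization denominator.
    """
    reads: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seq, copies = line.split("\t")[:2]
            reads[seq] = reads.get(seq, 0) + int(copies)
    return AgoLibrary(
        ago_id=ago_id, reads=reads, total_mapped=total_mapped or sum(reads.values())
    )
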