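"""Enrichment scoring of solved modules against the S_p / S_n partition."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

from .instance_model import CoverSolution, ValidationError
from .sga_preprocess import SignaturePartition, ValidSGAMap, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = ["ModuleReport", "module_enrichment_pvalue", "evaluate_module"]


@dataclass(frozen=True)
class ModuleReport:
    signature_id: str
    genes: Tuple[str, ...]
    coverage: int
    weight: float
    enrichment_p: float
    neg_log2_p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.enrichment_p <= 1.0):
            raise ValidationError(f"enrichment_p out of (0,1]: {self.enrichment_p}")


def module_enrichment_pvalue(
    genes: Sequence[str], sga: ValidSGAMap, partition: SignaturePartition
) -> float:
    """Pooled hypergeometric upper-tail p-value of a module's SGA events.

    A tumor counts once however many module genes hit it: with
    N = |S_p| + |S_n| and K = |S_p|, n is the number of tumors in the
    partition carrying at least one valid event of a module gene and k the
    number of those in S_p; returns P(X >= k).
    """
    if not partition.accepted:
        raise ValidationError(
            f"partition {partition.signature_id!r} is not accepted"
        )
    if not genes:
        raise ValidationError("module is empty")
    sp, sn = partition.sp, partition.sn
    hit: set = set()
    for gene in genes:
        hit |= sga.get(gene, frozenset())
    n = len(hit & (sp | sn))
    k = len(hit & sp)
    if n == 0:
        logger.warning("module hits no tumors in S_p | S_n; p-value set to 1.0")
        return 1.0
    return hypergeom_upper_tail(len(sp) + len(sn), len(sp), n, k)


def evaluate_module(
    signature_id: str,
    solution: CoverSolution,
    sga: ValidSGAMap,
    partition: SignaturePartition,
) -> ModuleReport:
    """Package a solved module with its enrichment p-value."""
    genes = solution.sorted_chosen()
    p = module_enrichment_pvalue(genes, sga, partition) if genes else 1.0
    return ModuleReport(
        signature_id=signature_id,
        genes=genes,
        coverage=solution.coverage,
        weight=solution.weight,
        enrichment_p=p,
        neg_log2_p=-math.log2(p),
    )
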