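"""Cohort preprocessing: valid SGA calling, signature partition, weights.

Turns a tumor cohort (non-silent mutation indicators, GISTIC scores, and
expression) plus a gene signature into a partition of tumors with abnormal
(S_p) versus normal-like (S_n) signature expression, a per-gene set of
tumors carrying valid somatic genome alterations, hypergeometric gene
weights, and finally a cover instance over S_p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .instance_model import CoverInstance, ValidationError, WeightedSet, normalize_instance

logger = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "ValidSGAMap",
    "SignaturePartition",
    "GeneWeight",
    "call_valid_sga",
    "filter_rare_genes",
    "fold_changes",
    "partition_tumors",
    "compute_weights",
    "select_candidates",
    "build_cover_instance",
    "hypergeom_upper_tail",
]

ValidSGAMap = Dict[str, FrozenSet[str]]

GISTIC_LEVELS = {-2, -1, 0, 1, 2}


@dataclass
class CohortData:
    """Aligned cohort tables: mutation and GISTIC are gene x tumor,
    expression is gene x sample (tumors and normals)."""

    mutation: pd.DataFrame
    gistic: pd.DataFrame
    expression: pd.DataFrame
    sample_type: pd.Series  # sample id -> "tumor" | "normal"

    def tumors(self) -> List[str]:
        return [s for s in self.sample_type.index if self.sample_type[s] == "tumor"]

    def normals(self) -> List[str]:
        return [s for s in self.sample_type.index if self.sample_type[s] == "normal"]

    def validate(self) -> None:
        bad_types = set(self.sample_type.unique()) - {"tumor", "normal"}
        if bad_types:
            raise ValidationError(f"unknown sample types: {sorted(bad_types)}")
        if not self.normals():
            raise ValidationError("at least one normal sample is required")
        tumors = set(self.tumors())
        if set(self.mutation.columns) != set(self.gistic.columns):
            raise ValidationError("mutation and GISTIC tumor columns differ")
        if not set(self.mutation.columns) <= tumors:
            raise ValidationError("mutation columns contain non-tumor samples")
        if not set(self.mutation.columns) <= set(self.expression.columns):
            raise ValidationError("expression is missing tumor columns")
        vals = set(pd.unique(self.gistic.values.ravel()))
        if not vals <= GISTIC_LEVELS:
            raise ValidationError(
                f"GISTIC values outside {{-2,-1,0,1,2}}: {sorted(vals - GISTIC_LEVELS)[:5]}"
            )
        mvals = set(pd.unique(self.mutation.values.ravel()))
        if not mvals <= {0, 1}:
            raise ValidationError("mutation matrix must be binary")


@dataclass(frozen=True)
class SignaturePartition:
    """Per-signature tumor split: S_p (abnormal) and S_n (normal-like)."""

    signature_id: str
    sp: FrozenSet[str]
    sn: FrozenSet[str]
    direction: Mapping[str, str]  # S_p tumor -> "up" | "down"
    status: str  # "accepted" | "rejected"
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass(frozen=True)
class GeneWeight:
    gene: str
    k_p: int
    k_n: int
    weight: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if N <= 0 or n <= 0:
        raise ValidationError("hypergeometric tail requires N > 0 and n > 0")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(0.0, p))


def call_valid_sga(cohort: CohortData, z_threshold: float = 1.64) -> ValidSGAMap:
    """Per gene, the tumors with a valid SGA event.

    Valid means a non-silent mutation, or a GISTIC score of +2 with an
    expression z-score >= ``z_threshold``, or -2 with z <= -``z_threshold``.
    The z background is the gene's expression over tumors with GISTIC 0;
    genes whose background has fewer than two tumors or zero spread have
    their CNV events skipped (mutations are unaffected).
    """
    cohort.validate()
    tumors = list(cohort.mutation.columns)
    result: Dict[str, set] = {}

    for gene in cohort.mutation.index:
        mut = cohort.mutation.loc[gene]
        hits = set(mut.index[mut == 1])
        if hits:
            result.setdefault(gene, set()).update(hits)

    expr_t = cohort.expression.reindex(columns=tumors)
    for gene in cohort.gistic.index:
        g = cohort.gistic.loc[gene]
        cnv_tumors = g.index[(g == 2) | (g == -2)]
        if len(cnv_tumors) == 0:
            continue
        if gene not in expr_t.index:
            logger.warning("gene %s has CNV calls but no expression; CNV skipped", gene)
            continue
        e = expr_t.loc[gene]
        background = e[g.index[g == 0]].dropna()
        if len(background) < 2:
            logger.warning(
                "gene %s: <2 GISTIC-0 tumors for background; CNV skipped", gene
            )
            continue
        mean = float(background.mean())
        sd = float(background.std(ddof=1))
        if sd == 0.0 or not math.isfinite(sd):
            logger.warning("gene %s: zero-spread background; CNV skipped", gene)
            continue
        for t in cnv_tumors:
            x = e.get(t)
            if x is None or pd.isna(x):
                continue
            z = (float(x) - mean) / sd
            if (g[t] == 2 and z >= z_threshold) or (g[t] == -2 and z <= -z_threshold):
                result.setdefault(gene, set()).add(t)

    return {gene: frozenset(ts) for gene, ts in result.items() if ts}


def filter_rare_genes(sga: ValidSGAMap, min_tumors: int = 6) -> ValidSGAMap:
    """Drop genes with valid events in fewer than ``min_tumors`` tumors
    (default: events in no more than five tumors are removed)."""
    return {g: ts for g, ts in sga.items() if len(ts) >= min_tumors}


def fold_changes(
    expression: pd.DataFrame,
    sample_type: pd.Series,
    pseudocount: float = 1.0,
    center: str = "median",
    log2_input: bool = False,
) -> pd.DataFrame:
    """Gene x tumor fold changes versus the normal-sample reference.

    The reference is the median (or mean) expression across normal samples;
    fold change is (tumor + eps) / (reference + eps) on a linear scale.
    """
    normals = [s for s in sample_type.index if sample_type[s] == "normal"]
    tumors = [s for s in sample_type.index if sample_type[s] == "tumor"]
    normals = [s for s in normals if s in expression.columns]
    tumors = [s for s in tumors if s in expression.columns]
    if not normals:
        raise ValidationError("fold_changes requires at least one normal sample")
    expr = expression
    if log2_input:
        expr = np.power(2.0, expr)
    if center == "median":
        ref = expr[normals].median(axis=1)
    elif center == "mean":
        ref = expr[normals].mean(axis=1)
    else:
        raise ValidationError(f"unknown center: {center!r}")
    denom = ref + pseudocount
    if (denom == 0).any():
        raise ValidationError(
            "zero reference with zero pseudocount; set pseudocount > 0"
        )
    folds = expr[tumors].add(pseudocount).div(denom, axis=0)
    return folds


def partition_tumors(
    signature_id: str,
    genes: Sequence[str],
    folds: pd.DataFrame,
    up_fold: float = 3.0,
    normal_fold: float = 2.0,
    sp_fraction: float = 0.75,
    sn_fraction: float = 0.5,
    subgroup_fraction: float = 0.10,
    min_sp_size: int = 30,
) -> SignaturePartition:
    """Split tumors into S_p / S_n for one signature.

    A tumor joins S_p if strictly more than ``sp_fraction`` of the signature
    genes change >= ``up_fold``-fold in the same direction, and S_n if at
    least ``sn_fraction`` of the genes change less than ``normal_fold``-fold.
    If the smaller of the up/down S_p sub-groups is below
    ``subgroup_fraction`` of the larger it is dropped; otherwise the
    signature is rejected.  Accepted only if |S_p| > ``min_sp_size``.
    """
    if not genes:
        raise ValidationError(f"signature {signature_id!r} is empty")
    present = [g for g in genes if g in folds.index]
    missing = set(genes) - set(present)
    if missing:
        logger.warning(
            "signature %s: %d gene(s) missing from expression, dropped: %s",
            signature_id, len(missing), sorted(missing)[:5],
        )
    if not present:
        return SignaturePartition(
            signature_id, frozenset(), frozenset(), {}, "rejected",
            "no signature genes present in expression",
        )

    sub = folds.loc[present]
    frac_up = (sub >= up_fold).mean(axis=0)
    frac_down = (sub <= 1.0 / up_fold).mean(axis=0)
    with np.errstate(divide="ignore"):
        magnitude = np.maximum(sub, 1.0 / sub)
    frac_small = (magnitude < normal_fold).mean(axis=0)

    up = {t for t in sub.columns if frac_up[t] > sp_fraction}
    down = {t for t in sub.columns if frac_down[t] > sp_fraction} - up
    sp = up | down
    sn = {t for t in sub.columns if frac_small[t] >= sn_fraction} - sp

    direction = {t: "up" for t in up}
    direction.update({t: "down" for t in down})

    if up and down:
        small, large = (up, down) if len(up) <= len(down) else (down, up)
        if len(small) < subgroup_fraction * len(large):
            logger.info(
                "signature %s: dropping %d tumor(s) in the smaller S_p sub-group",
                signature_id, len(small),
            )
            sp = set(large)
            direction = {t: d for t, d in direction.items() if t in sp}
        else:
            return SignaturePartition(
                signature_id, frozenset(sp), frozenset(sn), direction, "rejected",
                "signature both up- and down-regulated in comparable sub-groups",
            )

    if len(sp) <= min_sp_size:
        return SignaturePartition(
            signature_id, frozenset(sp), frozenset(sn), direction, "rejected",
            f"|S_p| = {len(sp)} <= {min_sp_size}",
        )
    return SignaturePartition(
        signature_id, frozenset(sp), frozenset(sn), direction, "accepted", None
    )


def compute_weights(
    sga: ValidSGAMap, partition: SignaturePartition
) -> List[GeneWeight]:
    """Hypergeometric upper-tail weight per gene with events in S_p | S_n.

    With N = |S_p| + |S_n| tumors, K = |S_p| marked, n_g event tumors among
    the N, and k_g of them in S_p, the weight is P(X >= k_g); smaller means
    the gene's events are more concentrated in S_p.
    """
    if not partition.accepted:
        raise ValidationError(
            f"partition {partition.signature_id!r} is not accepted"
        )
    sp, sn = partition.sp, partition.sn
    N = len(sp) + len(sn)
    K = len(sp)
    out: List[GeneWeight] = []
    for gene in sorted(sga):
        tumors = sga[gene]
        k_p = len(tumors & sp)
        k_n = len(tumors & sn)
        n_g = k_p + k_n
        if N == 0 or n_g == 0:
            continue
        w = hypergeom_upper_tail(N, K, n_g, k_p)
        out.append(GeneWeight(gene, k_p, k_n, w))
    return out


def select_candidates(
    weights: Sequence[GeneWeight], top_k: int = 200, max_weight: float = 0.2
) -> List[str]:
    """Genes with weight strictly below ``max_weight``, best-first, capped
    at ``top_k``."""
    eligible = sorted(
        (gw for gw in weights if gw.weight < max_weight),
        key=lambda gw: (gw.weight, gw.gene),
    )
    return [gw.gene for gw in eligible[:top_k]]


def build_cover_instance(
    partition: SignaturePartition,
    sga: ValidSGAMap,
    weights: Sequence[GeneWeight],
    candidates: Sequence[str],
) -> CoverInstance:
    """Cover instance over S_p: one set per candidate gene, elements the
    gene's valid-SGA tumors restricted to S_p, weight its gene weight."""
    if not partition.accepted:
        raise ValidationError(
            f"partition {partition.signature_id!r} is not accepted"
        )
    wmap = {gw.gene: gw.weight for gw in weights}
    sets = []
    for gene in candidates:
        restricted = sga.get(gene, frozenset()) & partition.sp
        if not restricted:
            continue
        sets.append(WeightedSet(gene, frozenset(restricted), wmap[gene]))
    return normalize_instance(CoverInstance.of(sets, universe=partition.sp))
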