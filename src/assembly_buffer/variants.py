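"""Spatial clustering and interface enrichment of pathogenic variants.

The extent-of-disease-clustering (EDC) statistic asks whether the known
pathogenic missense positions of a protein huddle together in 3D.  For
every confidently modelled residue (pLDDT > 50 when confidence scores are
present) the Cα distance to the nearest *other* disease residue is taken;
EDC is the ratio

    log10(mean nearest-disease distance over non-disease residues)
    ---------------------------------------------------------------
    log10(mean nearest-disease distance over disease residues)

Values above 1 indicate clustering (disease residues sit closer to each
other than the background does), values at or below 1 dispersion.  At least
three pathogenic missense positions are required, mirroring the inclusion
rule used when the metric is applied to clinical variant sets.

Predicted stability changes (ΔΔG, kcal/mol) are consumed as a precomputed
column of the variant table — they are never calculated here — and rows
with pLDDT < 50 are excluded from ΔΔG comparisons, since such residues are
likely disordered in solution and their predictions unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateLogError,
    DegenerateVarianceError,
    InclusionRuleError,
    ParameterError,
    ValidationError,
)
from .stats import EnrichmentResult, hypergeom_test, odds_ratio_ci
from .structures import Chain

PLDDT_THRESHOLD = 50.0
MIN_DISEASE_POSITIONS = 3


@dataclass
class MutationSet:
    """Missense variants of one protein.

    Positions are 1-based canonical residue indices; ``pathogenic`` flags
    each position; ``ddg`` (optional) is the externally predicted stability
    change per variant and ``plddt`` (optional) the model confidence at the
    variant's residue.
    """

    protein_id: str
    positions: np.ndarray
    pathogenic: np.ndarray
    ddg: np.ndarray | None = None
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.pathogenic = np.asarray(self.pathogenic, dtype=bool)
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValidationError("variant positions must be unique")
        if len(self.pathogenic) != len(self.positions):
            raise ValidationError("pathogenic flags must align with positions")
        if np.any(self.positions < 1):
            raise ValidationError("positions are 1-based")
        for name in ("ddg", "plddt"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != len(self.positions):
                    raise ValidationError(f"{name} must align with positions")
                setattr(self, name, arr)
        if self.ddg is not None and not np.all(np.isfinite(self.ddg)):
            raise ValidationError("ddg values must be finite where present")

    @property
    def pathogenic_positions(self) -> np.ndarray:
        return self.positions[self.pathogenic]

    def confident_ddg(self, plddt_threshold: float = PLDDT_THRESHOLD) -> np.ndarray:
        """ΔΔG of variants at confidently modelled residues (pLDDT >= cut)."""
        if self.ddg is None:
            raise ValidationError("mutation set carries no ddg column")
        if self.plddt is None:
            return self.ddg
        return self.ddg[self.plddt >= plddt_threshold]


def edc(
    chain: Chain,
    disease_positions,
    plddt_threshold: float = PLDDT_THRESHOLD,
) -> float:
    """Extent of disease clustering for one chain.

    Residues with pLDDT <= threshold are dropped when the chain carries
    confidence scores.  For disease residues the nearest-neighbour search
    excludes the residue itself (its self-distance of zero would make the
    log undefined).  Mean distances of 1 Å or less are rejected as corrupt
    input — impossible for Cα sets of three or more distinct residues.
    """
    disease = np.unique(np.asarray(list(disease_positions), dtype=int))
    coords = chain.ca_coords()
    rids = chain.residue_ids
    if chain.plddt is not None:
        keep = chain.plddt > plddt_threshold
        coords, rids = coords[keep], rids[keep]
    is_disease = np.isin(rids, disease)
    n_dis = int(is_disease.sum())
    if n_dis < MIN_DISEASE_POSITIONS:
        raise InclusionRuleError(
            f"need >= {MIN_DISEASE_POSITIONS} pathogenic positions after the "
            f"confidence filter, got {n_dis}"
        )
    d = cdist(coords, coords[is_disease])
    # a disease residue must not count itself as its nearest disease residue
    dis_rows = np.where(is_disease)[0]
    d[dis_rows, np.arange(n_dis)] = np.inf
    nearest = d.min(axis=1)
    mean_dis = float(nearest[is_disease].mean())
    mean_nondis = float(nearest[~is_disease].mean()) if (~is_disease).any() else np.nan
    if not np.isfinite(mean_nondis):
        raise InclusionRuleError("no non-disease residues left after filtering")
    if mean_dis <= 1.0 or mean_nondis <= 1.0:
        raise DegenerateLogError(
            f"mean nearest-disease distance <= 1 Å (disease {mean_dis:.3f}, "
            f"non-disease {mean_nondis:.3f}); check coordinates"
        )
    return float(np.log10(mean_nondis) / np.log10(mean_dis))


def interface_mutation_enrichment(
    mutations: MutationSet,
    interface_residues,
    chain_length: int,
) -> EnrichmentResult:
    """Hypergeometric enrichment of pathogenic positions at the interface.

    Compares the pathogenic-position rate on interface residues against the
    rest of the chain.  The point odds ratio is the raw cross-product (zero
    cells allowed, giving OR 0 or inf); the SE-method CI is reported only
    when all four cells are populated.
    """
    interface = np.unique(np.asarray(list(interface_residues), dtype=int))
    if interface.size == 0:
        raise ValidationError(
            "empty interface set: the subunit failed the minimum interface "
            "area rule upstream"
        )
    if len(mutations.positions) == 0 or not mutations.pathogenic.any():
        raise ValidationError("need at least one pathogenic mutation")
    if interface.max() > chain_length:
        raise ValidationError("interface residues exceed chain length")
    path = mutations.pathogenic_positions
    k1 = int(np.isin(path, interface).sum())
    n1 = int(interface.size)
    n2 = int(chain_length - interface.size)
    k2 = int(len(path) - k1)
    p = hypergeom_test(k1, n1, k2, n2)
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    try:
        orr, lo, hi = odds_ratio_ci(k1, n1, k2, n2)
    except Exception:
        orr = (a * d) / (b * c) if b * c > 0 else float("inf")
        lo = hi = float("nan")
    return EnrichmentResult(
        k1=k1,
        n1=n1,
        k2=k2,
        n2=n2,
        p1=k1 / n1,
        p2=k2 / n2,
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        method="hypergeometric interface enrichment",
    )


@dataclass
class GroupComparison:
    """Two-sample rank-test result with the z-based effect size."""

    p_value: float
    effect_size_r: float
    z: float
    n: int
    method: str


def compare_group_metric(
    values_a,
    values_b,
    method: str = "asymptotic",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two numeric vectors.

    Default is the normal approximation with continuity correction and
    average ranks for ties; ``method="exact"`` switches to the exact null
    distribution (small samples, no ties).  The effect size is r = z/√n
    with z recovered from the two-sided p-value and n the pooled sample
    size, signed by the direction of the observed rank shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateVarianceError("all values tied; rank test undefined")
    if method not in {"asymptotic", "exact"}:
        raise ParameterError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    n = a.size + b.size
    mean_u = a.size * b.size / 2
    direction = np.sign(res.statistic - mean_u)
    p = float(res.pvalue)
    z = float(sps.norm.isf(min(p, 1.0) / 2)) * (direction if direction != 0 else 0.0)
    return GroupComparison(
        p_value=p,
        effect_size_r=float(z / np.sqrt(n)),
        z=z,
        n=n,
        method=f"wilcoxon-{method}",
    )
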