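"""Enrichment and resampling statistics for gene-level comparisons.

This layer answers questions of the form "is cotranslational assembly rarer
in group A than in group B?" for groups of genes defined by inheritance
mode, molecular mechanism, abundance quartile, symmetry group or chromosome:

* one-sided hypergeometric test on the 2x2 of co-assembly by group;
* odds ratio with the SE-method 95% CI, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d));
* 68% Jeffreys binomial credible intervals, Beta(k+½, n-k+½) quantiles, for
  per-bar uncertainty;
* Fisher's exact test for small composition tables;
* Holm-Bonferroni familywise correction;
* a stratified bootstrap of interface shifts with percentile CIs and a
  finite-sample-corrected resampling p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, ValidationError, ZeroCellError

INHERITANCE_MODES = {"AD", "AR", "XLD", "XLR", "none"}
MECHANISMS = {"DN", "GOF", "LOF", "unclassified"}
OLIGOMER_CLASSES = {"pdb_homomer", "other_homomer", "repeated_subunit", "monomer"}
SYMMETRY_GROUPS = {"C2", "Cn>2", "Dn>1", "other", "NA"}
FUNCTIONAL_CLASSES = {
    "transporter",
    "metabolic_enzyme",
    "tf_chromatin",
    "known_other",
    "unknown",
}


@dataclass
class GeneRecord:
    """One gene's annotations for the enrichment analyses.

    ``coassembly`` flags experimentally detected cotranslational assembly;
    ``mechanism`` is only meaningful for autosomal-dominant genes (the
    classification targets dominant disorders), hence the invariant that a
    classified mechanism implies AD inheritance.
    """

    gene_id: str
    inheritance: str = "none"
    mechanism: str = "unclassified"
    coassembly: bool = False
    oligomer_class: str = "pdb_homomer"
    symmetry: str = "NA"
    abundance_ppm: float | None = None
    functional_class: str = "unknown"
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValidationError(f"unknown inheritance {self.inheritance!r}")
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if self.oligomer_class not in OLIGOMER_CLASSES:
            raise ValidationError(f"unknown oligomer class {self.oligomer_class!r}")
        if self.symmetry not in SYMMETRY_GROUPS:
            raise ValidationError(f"unknown symmetry {self.symmetry!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(f"unknown functional class {self.functional_class!r}")
        if self.oligomer_class == "monomer" and self.symmetry != "NA":
            raise ValidationError("monomers must have symmetry NA")
        if self.mechanism != "unclassified" and self.inheritance != "AD":
            raise ValidationError("mechanism classes apply to AD genes only")
        if self.abundance_ppm is not None and self.abundance_ppm < 0:
            raise ValidationError("abundance_ppm must be >= 0")


@dataclass
class EnrichmentResult:
    """Two-group contingency comparison: k1/n1 vs k2/n2 successes."""

    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


@dataclass
class BootstrapShiftResult:
    """Stratified bootstrap summary of an interface shift (percent units)."""

    stratum: str
    point_shift: float
    ci_low: float
    ci_high: float
    p_boot: float
    B: int


def _validate_counts(k: int, n: int, name: str = "group") -> None:
    if n <= 0:
        raise ParameterError(f"{name}: group size must be positive")
    if not 0 <= k <= n:
        raise ParameterError(f"{name}: need 0 <= k <= n, got k={k}, n={n}")


def hypergeom_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "observed"
) -> float:
    """Hypergeometric test comparing success rates k1/n1 vs k2/n2.

    Draws n1 from the pooled urn of k1+k2 successes among n1+n2 items and
    asks how probable a deviation at least as extreme as k1 is.  The default
    ``alternative="observed"`` tests one-sided in the direction of the
    observed deviation; "less" and "greater" force a direction.
    """
    _validate_counts(k1, n1, "group 1")
    _validate_counts(k2, n2, "group 2")
    dist = sps.hypergeom(M=n1 + n2, n=k1 + k2, N=n1)
    if alternative == "observed":
        alternative = "less" if k1 / n1 <= k2 / n2 else "greater"
    if alternative == "less":
        return float(dist.cdf(k1))
    if alternative == "greater":
        return float(dist.sf(k1 - 1))
    raise ParameterError(f"unknown alternative {alternative!r}")


def odds_ratio_ci(
    k1: int | None = None,
    n1: int | None = None,
    k2: int | None = None,
    n2: int | None = None,
    p1: float | None = None,
    p2: float | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Odds ratio with the SE-method confidence interval.

    With counts, OR = (a·d)/(b·c) for the 2x2 (a=k1, b=n1-k1, c=k2, d=n2-k2)
    and CI = exp(ln OR ± z·√(1/a+1/b+1/c+1/d)).  With proportions only, the
    point OR [p1/(1-p1)]/[p2/(1-p2)] is returned and the CI is NaN.  Zero
    cells raise :class:`ZeroCellError`; no continuity correction is applied.
    """
    if p1 is not None or p2 is not None:
        if p1 is None or p2 is None:
            raise ParameterError("need both proportions")
        if not (0 < p1 < 1 and 0 < p2 < 1):
            raise ParameterError("proportions must be in (0, 1)")
        orr = (p1 / (1 - p1)) / (p2 / (1 - p2))
        return float(orr), float("nan"), float("nan")
    _validate_counts(k1, n1, "group 1")
    _validate_counts(k2, n2, "group 2")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    if min(a, b, c, d) == 0:
        raise ZeroCellError(f"zero cell in 2x2 table ({a}, {b}; {c}, {d})")
    orr = (a * d) / (b * c)
    z = sps.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(orr), float(orr * np.exp(-z * se)), float(orr * np.exp(z * se))


def jeffreys_interval(k: int, n: int, level: float = 0.68) -> tuple[float, float]:
    """Equal-tailed Jeffreys binomial credible interval.

    Quantiles of Beta(k+½, n-k+½) at (1-level)/2 and 1-(1-level)/2; the 68%
    default mirrors one-standard-error bars on proportion plots.
    """
    _validate_counts(k, n)
    alpha = (1 - level) / 2
    dist = sps.beta(k + 0.5, n - k + 0.5)
    return float(dist.ppf(alpha)), float(dist.ppf(1 - alpha))


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table (a, b; c, d).

    Returns (sample odds ratio, p).  P sums the probabilities of all tables
    with the same margins that are no more probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ParameterError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ParameterError("empty table")
    orr, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down familywise-error-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must be in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="holm")[1]


def group_compare(
    records: Iterable[GeneRecord],
    predicate_a: Callable[[GeneRecord], bool],
    predicate_b: Callable[[GeneRecord], bool],
    outcome: Callable[[GeneRecord], bool] = lambda r: r.coassembly,
    level: float = 0.95,
) -> EnrichmentResult | None:
    """Compare an outcome rate between two predicates over a gene table.

    Builds the 2x2 of outcome by group, then delegates to
    :func:`hypergeom_test` (one-sided, observed direction) and
    :func:`odds_ratio_ci`.  An empty stratum is skipped with a warning
    (returns None) so that panel-style sweeps over many strata keep going.
    """
    records = list(records)
    group_a = [r for r in records if predicate_a(r)]
    group_b = [r for r in records if predicate_b(r)]
    if not group_a or not group_b:
        warnings.warn("empty stratum; comparison skipped", stacklevel=2)
        return None
    k1 = sum(bool(outcome(r)) for r in group_a)
    k2 = sum(bool(outcome(r)) for r in group_b)
    n1, n2 = len(group_a), len(group_b)
    p = hypergeom_test(k1, n1, k2, n2)
    orr, lo, hi = odds_ratio_ci(k1, n1, k2, n2, level=level)
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
        method="hypergeometric + SE-method CI",
    )


def abundance_quartiles(records: Sequence[GeneRecord]) -> dict[str, int]:
    """Assign abundance quartiles (1 = lowest) with equal-count bins.

    Records lacking abundance are excluded.  Ties are broken by the stable
    input order so the split is deterministic; bin sizes differ by at most
    one.  Returns ``{gene_id: quartile}``.
    """
    with_ab = [(i, r) for i, r in enumerate(records) if r.abundance_ppm is not None]
    if len(with_ab) < 4:
        raise ParameterError("need at least 4 records with abundance")
    order = sorted(range(len(with_ab)), key=lambda j: (with_ab[j][1].abundance_ppm, j))
    bins = np.array_split(order, 4)
    out: dict[str, int] = {}
    for q, idxs in enumerate(bins, start=1):
        for j in idxs:
            out[with_ab[j][1].gene_id] = q
    return out


#: Default total cellular protein concentration in nM (≈2.7 mM), used to
#: turn parts-per-million abundances into approximate molar concentrations.
TOTAL_PROTEIN_NM = 2.7e6


def ppm_to_molar(ppm, total_protein_molar: float = TOTAL_PROTEIN_NM):
    """Convert ppm protein abundance to approximate concentration in nM.

    Linear transform ppm·total·10⁻⁶ where ``total_protein_molar`` is the
    total protein concentration of the cell in nM.  Only the ordering of
    abundances matters downstream (quartile binning), so the constant is a
    configurable scale, not a fitted quantity.
    """
    arr = np.asarray(ppm, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("ppm must be non-negative")
    out = arr * total_protein_molar * 1e-6
    return float(out) if np.isscalar(ppm) else out


def bootstrap_shift(
    observations: Iterable[tuple[str, float]],
    basemean: float | Mapping[str, float],
    B: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
) -> dict[str, BootstrapShiftResult]:
    """Stratified bootstrap of the mean interface shift per stratum.

    ``observations`` are (stratum, relative interface location) pairs;
    ``basemean`` is the expected relative location (scalar, or per-stratum
    mapping) computed once on the full dataset.  Within each stratum the
    shift values (observed - basemean, reported in percent of length) are
    resampled with replacement B times; the point estimate of each resample
    is its mean.  The CI is the percentile interval and the one-sided
    p-value for a C-terminal (positive) shift is (1 + #{resample means <=
    0})/(B + 1), the add-one rule correcting for finite resampling.
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[float]] = {}
    for stratum, ril in observations:
        base = basemean[stratum] if isinstance(basemean, Mapping) else basemean
        strata.setdefault(stratum, []).append(100.0 * (ril - base))
    results: dict[str, BootstrapShiftResult] = {}
    alpha = (1 - level) / 2
    for stratum, shifts in strata.items():
        arr = np.asarray(shifts)
        if arr.size == 0:
            warnings.warn(f"empty stratum {stratum!r}; skipped", stacklevel=2)
            continue
        idx = rng.integers(0, arr.size, size=(B, arr.size))
        means = arr[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha, 1 - alpha])
        p_boot = (1 + int(np.sum(means <= 0))) / (B + 1)
        results[stratum] = BootstrapShiftResult(
            stratum=stratum,
            point_shift=float(arr.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            p_boot=float(p_boot),
            B=B,
        )
    return results
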