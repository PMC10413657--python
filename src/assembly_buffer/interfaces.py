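"""Interface area profiles and interface-location metrics.

The interface area of a subunit is the solvent-accessible surface area it
loses upon complex formation: per residue, ΔSASA = SASA(isolated subunit) -
SASA(subunit within the full complex), floored at zero.  Subunits whose
total interface area does not exceed 400 Å² are flagged as failing the
inclusion rule used to screen out likely crystallographic contacts.

Location metrics summarize where along the sequence the interface sits:

* ``relative_interface_location`` — interface-area-weighted mean of the
  relative residue positions i/L; 0 means fully N-terminal, 1 fully
  C-terminal.  N-terminally located interfaces can start forming while the
  chain is still on the ribosome, favouring cotranslational assembly.
* ``half_area_position`` — the relative chain position at which a growing
  nascent chain would first have exposed a given fraction (default half) of
  its final interface area.
* ``interface_shift`` — departure of an observed relative location from a
  reference (e.g. the mean of the subunit's symmetry group), in percent of
  protein length; positive values mean the interface is C-terminally
  shifted relative to expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedMetricError, ValidationError
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, compute_sasa
from .structures import ComplexStructure

#: Minimum total interface area (Å²) for a subunit to count as interacting.
MIN_INTERFACE_AREA = 400.0


@dataclass
class InterfaceProfile:
    """Per-residue interface area for one subunit of a complex."""

    chain_id: str
    length: int
    residue_ids: np.ndarray
    per_residue_area: np.ndarray
    min_area: float = MIN_INTERFACE_AREA
    total_area: float = field(init=False)
    passes_min_area: bool = field(init=False)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.per_residue_area = np.asarray(self.per_residue_area, dtype=float)
        if len(self.residue_ids) != len(self.per_residue_area):
            raise ValidationError("residue_ids and per_residue_area must align")
        if np.any(self.per_residue_area < 0):
            raise ValidationError("interface areas must be non-negative")
        self.total_area = float(self.per_residue_area.sum())
        self.passes_min_area = self.total_area > self.min_area

    def interface_residues(self, min_residue_area: float = 0.0) -> np.ndarray:
        """Residue indices with interface area strictly above a floor."""
        return self.residue_ids[self.per_residue_area > min_residue_area]


def interface_profile(
    structure: ComplexStructure,
    subject_chain: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    min_area: float = MIN_INTERFACE_AREA,
) -> InterfaceProfile:
    """ΔSASA profile of one subunit against all other chains of the complex.

    For complexes with more than two chains the subject chain's profile
    accumulates area lost to the full complement of partners, i.e. the sum
    over all pairwise interfaces the subject participates in.
    """
    if len(structure.chains) < 2:
        raise ValidationError(
            "interface is undefined for a single-chain structure"
        )
    chain = structure.chain(subject_chain)
    isolated = compute_sasa(chain, probe_radius, n_points)[subject_chain]
    in_complex = compute_sasa(structure, probe_radius, n_points)[subject_chain]
    delta = np.clip(isolated - in_complex, 0.0, None)
    return InterfaceProfile(
        chain_id=subject_chain,
        length=chain.length,
        residue_ids=chain.residue_ids,
        per_residue_area=delta,
        min_area=min_area,
    )


def relative_interface_location(profile: InterfaceProfile) -> float:
    """Area-weighted mean relative sequence position of the interface.

    Returns Σᵢ aᵢ·(i/L) / Σᵢ aᵢ with i the 1-based canonical residue index
    and L the chain length; in [0, 1], N terminus → 0, C terminus → 1.
    """
    if profile.total_area <= 0:
        raise UndefinedMetricError(
            "relative interface location undefined for zero interface area"
        )
    rel = profile.residue_ids / profile.length
    return float(np.sum(profile.per_residue_area * rel) / profile.total_area)


def half_area_position(profile: InterfaceProfile, fraction: float = 0.5) -> float:
    """Relative position where cumulative interface area reaches a fraction.

    Returns the smallest i/L such that the area over residues 1..i is at
    least ``fraction`` of the total — the point during translation at which
    that share of the final interface has been exposed.
    """
    if profile.total_area <= 0:
        raise UndefinedMetricError(
            "half-area position undefined for zero interface area"
        )
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    cum = np.cumsum(profile.per_residue_area)
    target = fraction * profile.total_area
    # first residue whose cumulative area crosses the target; tolerate
    # floating error at fraction=1 where cum[-1] == target
    idx = int(np.searchsorted(cum, target - 1e-9 * profile.total_area))
    idx = min(idx, len(cum) - 1)
    return float(profile.residue_ids[idx] / profile.length)


def interface_shift(observed: float, basemean: float) -> float:
    """Observed minus expected relative interface location, in percent.

    ``basemean`` is the reference mean relative location (typically the mean
    of the subunit's symmetry group).  +6 means the interface is 6% of the
    protein's length more C-terminal than expected.
    """
    if not (0 <= observed <= 1 and 0 <= basemean <= 1):
        raise ParameterError("locations must be in [0, 1]")
    return 100.0 * (observed - basemean)
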