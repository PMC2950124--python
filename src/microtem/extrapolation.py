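"""Hemisphere-level extrapolation of microvolume densities.

Dense microvolume reconstructions yield per-µm³ densities of presynaptic
sites, axonal branch points, and axonal cable.  Multiplying the averaged
densities by the neuropile volume of a brain hemisphere (~20,000 µm³ for the
first-instar larva) gives whole-hemisphere totals, and dividing by the
neuron count (~1,500 per hemisphere) gives per-neuron averages.  Unit-cube
conversion re-expresses cable density as millimetres of cable per cube of a
chosen side length, the standard form for cross-species comparison.

Rounding conventions follow the reporting precision of such estimates:
per-neuron counts round half-up to integers, per-neuron lengths to one
significant figure, densities to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

__all__ = [
    "DensityTriple",
    "BrainEstimate",
    "round_half_up",
    "round_sig",
    "average_densities",
    "extrapolate_totals",
    "per_neuron",
    "scale_cable_density",
    "cube_side_from_volume",
    "estimate_brain",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (26.67→27, 10.5→11)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (38.67 → 40 at one figure)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - sig + 1)
    return round_half_up(x / q) * q


@dataclass(frozen=True)
class DensityTriple:
    """Per-µm³ densities: presynaptic sites, axonal branch points, cable.

    ``cable`` is axonal cable length density in µm per µm³.
    """

    presynapse: float
    branch_point: float
    cable: float

    def __post_init__(self) -> None:
        if min(self.presynapse, self.branch_point, self.cable) < 0:
            raise ValueError("densities must be non-negative")

    def rounded(self) -> "DensityTriple":
        """Densities at one significant figure (reporting precision)."""
        return DensityTriple(
            round_sig(self.presynapse), round_sig(self.branch_point), round_sig(self.cable)
        )


@dataclass(frozen=True)
class BrainEstimate:
    """Hemisphere totals and per-neuron averages (raw and rounded)."""

    hemisphere_volume_um3: float
    n_neurons: int
    total_presynapses: float
    total_branch_points: float
    total_cable_um: float
    presynapses_per_neuron: float
    branches_per_neuron: float
    cable_um_per_neuron: float
    presynapses_per_neuron_rounded: int
    branches_per_neuron_rounded: int
    cable_um_per_neuron_rounded: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def average_densities(per_microvolume: Sequence[DensityTriple]) -> DensityTriple:
    """Arithmetic mean of per-microvolume density triples."""
    if not per_microvolume:
        raise ValueError("need at least one microvolume")
    n = len(per_microvolume)
    return DensityTriple(
        sum(d.presynapse for d in per_microvolume) / n,
        sum(d.branch_point for d in per_microvolume) / n,
        sum(d.cable for d in per_microvolume) / n,
    )


def extrapolate_totals(densities: DensityTriple, volume_um3: float) -> Dict[str, float]:
    """Component-wise density × volume: whole-hemisphere totals."""
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    return {
        "presynapses": densities.presynapse * volume_um3,
        "branch_points": densities.branch_point * volume_um3,
        "cable_um": densities.cable * volume_um3,
    }


def per_neuron(totals: Dict[str, float], n_neurons: int) -> Dict[str, float]:
    """Per-neuron averages, raw and under the reporting rounding rules.

    Counts (presynapses, branches) round half-up to integers; cable length
    rounds to one significant figure.
    """
    if n_neurons <= 0:
        raise ValueError("neuron count must be > 0")
    raw = {k: v / n_neurons for k, v in totals.items()}
    return {
        "presynapses": raw["presynapses"],
        "branch_points": raw["branch_points"],
        "cable_um": raw["cable_um"],
        "presynapses_rounded": round_half_up(raw["presynapses"]),
        "branch_points_rounded": round_half_up(raw["branch_points"]),
        "cable_um_rounded": round_sig(raw["cable_um"]),
    }


def cube_side_from_volume(volume_um3: float) -> float:
    """Side of the cube with the given volume (µm)."""
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    return volume_um3 ** (1.0 / 3.0)


def scale_cable_density(
    length_um: float, reference_side_um: float, target_side_um: float
) -> float:
    """Cable length (µm) in a target cube, scaled from a reference cube.

    Homogeneous of degree 3 in ``target_side / reference_side``: a cable
    length measured in a cube of side ``reference_side_um`` is scaled to the
    cube of side ``target_side_um``.  Use :func:`cube_side_from_volume` for
    non-cubic reference volumes.
    """
    if reference_side_um <= 0 or target_side_um <= 0:
        raise ValueError("cube sides must be > 0")
    if length_um < 0:
        raise ValueError("length must be non-negative")
    return length_um * (target_side_um / reference_side_um) ** 3


def estimate_brain(
    densities: DensityTriple,
    hemisphere_volume_um3: float = 20_000.0,
    n_neurons: int = 1_500,
) -> BrainEstimate:
    """Full hemisphere extrapolation: totals plus per-neuron averages."""
    totals = extrapolate_totals(densities, hemisphere_volume_um3)
    per = per_neuron(totals, n_neurons)
    return BrainEstimate(
        hemisphere_volume_um3=hemisphere_volume_um3,
        n_neurons=n_neurons,
        total_presynapses=totals["presynapses"],
        total_branch_points=totals["branch_points"],
        total_cable_um=totals["cable_um"],
        presynapses_per_neuron=per["presynapses"],
        branches_per_neuron=per["branch_points"],
        cable_um_per_neuron=per["cable_um"],
        presynapses_per_neuron_rounded=per["presynapses_rounded"],
        branches_per_neuron_rounded=per["branch_points_rounded"],
        cable_um_per_neuron_rounded=per["cable_um_rounded"],
    )
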