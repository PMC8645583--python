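"""Scalp montage handling for the 10-20 / 10-10 electrode system.

Electrode positions are stored as 2-D coordinates on a unit-circle head
layout (azimuthal-equidistant projection of the standard spherical
positions; +y is anterior, +x is the subject's right, Cz near the origin,
the 10% ring at radius ~1).  Mastoids (M1/M2) fall outside the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Montage",
    "STANDARD_64",
    "TEST_19_LABELS",
    "DEFAULT_EXCLUDED",
    "electrode_region",
]

#: Channels the benchmark drops before analysis: the frontal-most
#: electrodes mechanically interfere with a head-mounted display and the
#: mastoids are chronically high-impedance on wet-gel caps.
DEFAULT_EXCLUDED = ("Fz", "F1", "F2", "M1", "M2")

# 64-channel layout of a standard 10-10 EEG cap (x right, y anterior).
_POS64 = {
    "Fp1": (-0.348, +0.991),
    "Fpz": (+0.001, +1.012),
    "Fp2": (+0.349, +0.990),
    "F7": (-0.931, +0.563),
    "F3": (-0.458, +0.484),
    "Fz": (+0.002, +0.460),
    "F4": (+0.472, +0.494),
    "F8": (+0.930, +0.566),
    "FC5": (-0.787, +0.190),
    "FC1": (-0.249, +0.190),
    "FC2": (+0.257, +0.195),
    "FC6": (+0.791, +0.198),
    "M1": (-1.231, -0.643),
    "T7": (-1.050, -0.200),
    "C3": (-0.502, -0.089),
    "Cz": (+0.003, -0.058),
    "C4": (+0.515, -0.084),
    "T8": (+1.053, -0.186),
    "M2": (+1.231, -0.646),
    "CP5": (-0.685, -0.401),
    "CP1": (-0.220, -0.293),
    "CP2": (+0.237, -0.291),
    "CP6": (+0.699, -0.387),
    "P7": (-0.713, -0.723),
    "P3": (-0.369, -0.549),
    "Pz": (+0.002, -0.494),
    "P4": (+0.383, -0.540),
    "P8": (+0.718, -0.718),
    "POz": (+0.001, -0.707),
    "O1": (-0.241, -0.921),
    "Oz": (+0.001, -0.919),
    "O2": (+0.245, -0.920),
    "AF7": (-0.672, +0.841),
    "AF3": (-0.338, +0.771),
    "AF4": (+0.351, +0.763),
    "AF8": (+0.673, +0.840),
    "F5": (-0.696, +0.519),
    "F1": (-0.224, +0.464),
    "F2": (+0.240, +0.469),
    "F6": (+0.708, +0.519),
    "FC3": (-0.511, +0.193),
    "FCz": (+0.003, +0.191),
    "FC4": (+0.521, +0.198),
    "C5": (-0.770, -0.132),
    "C1": (-0.243, -0.067),
    "C2": (+0.256, -0.065),
    "C6": (+0.779, -0.119),
    "CP3": (-0.449, -0.332),
    "CPz": (+0.002, -0.283),
    "CP4": (+0.465, -0.326),
    "P5": (-0.547, -0.620),
    "P1": (-0.181, -0.508),
    "P2": (+0.198, -0.501),
    "P6": (+0.552, -0.618),
    "PO5": (-0.384, -0.788),
    "PO3": (-0.268, -0.741),
    "PO4": (+0.271, -0.744),
    "PO6": (+0.393, -0.784),
    "FT7": (-1.070, +0.187),
    "FT8": (+1.067, +0.201),
    "TP7": (-0.920, -0.499),
    "TP8": (+0.924, -0.492),
    "PO7": (-0.482, -0.858),
    "PO8": (+0.488, -0.855),
}

#: Reduced 19-channel layout used by the fast simulation preset.  Covers
#: every scalp region and keeps the electrodes the benchmark singles out
#: (Cz reference, O1/O2 for alpha, C6/CP4 for the SEP components).
TEST_19_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8",
    "FC1", "FC2", "C3", "Cz", "C4", "C6",
    "CPz", "CP4", "P3", "Pz", "P4", "O1", "O2",
)


def electrode_region(label: str) -> str:
    """Coarse scalp region for a 10-20 style label."""
    u = label.upper()
    if u.startswith(("FP", "AF")):
        return "frontal"
    if u.startswith(("FT", "TP", "T", "M")):
        return "temporal"
    if u.startswith("FC"):
        return "central"
    if u.startswith("CP"):
        return "parietal"
    if u.startswith(("PO", "O")):
        return "occipital"
    if u.startswith("F"):
        return "frontal"
    if u.startswith("C"):
        return "central"
    if u.startswith("P"):
        return "parietal"
    raise ValueError(f"unrecognised electrode label: {label!r}")


@dataclass(frozen=True)
class Montage:
    """2-D head layout: label -> (x, y) plus a region tag per electrode."""

    positions: dict[str, tuple[float, float]]
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.regions:
            object.__setattr__(
                self,
                "regions",
                {lab: electrode_region(lab) for lab in self.positions},
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def position(self, label: str) -> tuple[float, float]:
        return self.positions[label]

    def region(self, label: str) -> str:
        return self.regions[label]

    def subset(self, labels) -> "Montage":
        missing = [l for l in labels if l not in self.positions]
        if missing:
            raise KeyError(f"labels not in montage: {missing}")
        return Montage({l: self.positions[l] for l in labels})

    def by_region(self, region: str) -> tuple[str, ...]:
        return tuple(l for l in self.positions if self.regions[l] == region)


#: The full 64-channel cap used at acquisition scale.
STANDARD_64 = Montage(dict(_POS64))
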