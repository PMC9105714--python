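"""Glycosaminoglycan (GAG) decasaccharide presets and the methylene blue template.

Seven GAG chains are modelled as coarse linear scaffolds whose only
analysis-relevant content is the inventory and position of their anionic
sites: sulfate groups of four chemical types (N-, 2-O-, 4-O-, 6-O-) anchored
at the sulfate sulfur, and one carboxylate per uronic-acid residue anchored
at the carboxyl carbon.  The presets:

========  =======================================  ==========  =============
preset    repeat disaccharide (sulfation)          n_SO3 dp10  charge/disacch
========  =======================================  ==========  =============
HP        GlcNS(6S)-IdoA(2S)  (tri-sulfated)          15            -4
deHP      fully desulfated heparin                     0            -1
CS4       GalNAc(4S)-GlcA                              5            -2
CS6       GalNAc(6S)-GlcA                              5            -2
HS1       GlcNS-IdoA(2S)                              10            -3
HS2       GlcNS(6S)-IdoA                              10            -3
HS3       GlcNAc(6S)-IdoA(2S)                         10            -3
========  =======================================  ==========  =============

Methylene blue (MB) is a rigid planar tricyclic monocation; the atoms that
matter downstream are the ring atoms (defining the aromatic plane) and the
two terminal dimethylamino nitrogens (defining the long axis and carrying
the most positive charge, hence anchoring electrostatic contacts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SITE_TYPES",
    "SULFATE_TYPES",
    "PRESETS",
    "AnionicSite",
    "GAGChain",
    "MBMolecule",
    "Pose",
    "build_gag",
    "count_anionic_sites",
]

SITE_TYPES = ("N-sulfate", "2-O-sulfate", "4-O-sulfate", "6-O-sulfate", "carboxylate")
SULFATE_TYPES = SITE_TYPES[:4]

#: sulfate types carried by one repeat disaccharide of each preset
PRESETS: dict[str, tuple[str, ...]] = {
    "HP": ("N-sulfate", "6-O-sulfate", "2-O-sulfate"),
    "deHP": (),
    "CS4": ("4-O-sulfate",),
    "CS6": ("6-O-sulfate",),
    "HS1": ("N-sulfate", "2-O-sulfate"),
    "HS2": ("N-sulfate", "6-O-sulfate"),
    "HS3": ("6-O-sulfate", "2-O-sulfate"),
}

# sulfates attached to the hexosamine ring (odd residues); 2-O-sulfate and the
# carboxylate sit on the uronic acid (even residues)
_HEXOSAMINE_SULFATES = frozenset({"N-sulfate", "4-O-sulfate", "6-O-sulfate"})

_ANCHOR_LABELS = {
    "N-sulfate": "sulfate_S",
    "2-O-sulfate": "sulfate_S",
    "4-O-sulfate": "sulfate_S",
    "6-O-sulfate": "sulfate_S",
    "carboxylate": "carboxylate_C",
}

#: backbone bead spacing along the chain axis (Angstrom)
BACKBONE_SPACING = 5.0
#: radial offset of anionic-site anchors from the backbone (Angstrom)
SITE_RADIUS = 4.0

_CC_BOND = 1.39  # aromatic C-C bond length, Angstrom
_N_OFFSET = 1.35  # terminal N distance outside the terminal ring, Angstrom


@dataclass(frozen=True)
class AnionicSite:
    """One typed anionic site on a GAG chain.

    ``anchor_label`` is determined by ``site_type``: sulfates are measured at
    the sulfate sulfur (``sulfate_S``), carboxylates at the carboxyl carbon
    (``carboxylate_C``).
    """

    site_type: str
    residue_index: int  # 1-based monosaccharide index along the chain
    anchor_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(
                f"unknown site_type {self.site_type!r}; valid: {SITE_TYPES}"
            )
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")
        object.__setattr__(self, "anchor_label", _ANCHOR_LABELS[self.site_type])


@dataclass
class GAGChain:
    """A GAG oligosaccharide as a coarse helical-axis scaffold.

    dp counts monosaccharides (dp10 = 5 disaccharides).  Backbone beads are
    laid every 5.0 A along the chain axis; each anionic site is offset 4.0 A
    radially from its residue's bead, with alternating phase between
    consecutive residues and a 120 degree sub-offset between sites sharing a
    residue (so distinct site types are spatially separable).
    """

    preset_name: str
    dp: int
    sites: list[AnionicSite]
    net_charge_per_disaccharide: int

    @property
    def n_disaccharides(self) -> int:
        return self.dp // 2

    @property
    def n_sulfates(self) -> int:
        return sum(1 for s in self.sites if s.site_type in SULFATE_TYPES)

    @property
    def n_carboxylates(self) -> int:
        return sum(1 for s in self.sites if s.site_type == "carboxylate")

    # ---- geometry -------------------------------------------------------

    def backbone_coords(self, bend: float = 0.0) -> np.ndarray:
        """Backbone bead positions, shape (dp, 3).

        ``bend`` is the total tangent turn (radians) distributed uniformly
        over the dp-1 segments; 0 gives a straight chain along +z.  The bend
        lies in the xz-plane.
        """
        n_seg = self.dp - 1
        headings = _segment_headings(n_seg, bend)
        steps = BACKBONE_SPACING * np.stack(
            [np.sin(headings), np.zeros(n_seg), np.cos(headings)], axis=1
        )
        coords = np.zeros((self.dp, 3))
        coords[1:] = np.cumsum(steps, axis=0)
        return coords

    def site_coords(self, bend: float = 0.0) -> np.ndarray:
        """Anchor positions of ``self.sites`` in order, shape (n_sites, 3)."""
        backbone = self.backbone_coords(bend)
        n_seg = self.dp - 1
        headings = _segment_headings(n_seg, bend)
        # heading of the residue's local frame: adjacent segment's heading
        res_heading = np.empty(self.dp)
        res_heading[:-1] = headings
        res_heading[-1] = headings[-1]

        out = np.empty((len(self.sites), 3))
        for i, site in enumerate(self.sites):
            r = site.residue_index
            phi = self.site_azimuth(site)
            alpha = res_heading[r - 1]
            # local frame at the bead: u in the bend plane, v out of it
            u = np.array([np.cos(alpha), 0.0, -np.sin(alpha)])
            v = np.array([0.0, 1.0, 0.0])
            out[i] = backbone[r - 1] + SITE_RADIUS * (
                np.cos(phi) * u + np.sin(phi) * v
            )
        return out

    def site_azimuth(self, site: AnionicSite) -> float:
        """Azimuth (radians) of a site around the chain axis.

        Phase alternates by 180 degrees between consecutive residues; sites
        sharing a residue are separated by 120 degrees in order of their
        appearance in SITE_TYPES.
        """
        same_res = [s for s in self.sites if s.residue_index == site.residue_index]
        same_res.sort(key=lambda s: SITE_TYPES.index(s.site_type))
        k = same_res.index(site)
        return np.pi * (site.residue_index - 1) + k * (2.0 * np.pi / 3.0)


def _segment_headings(n_seg: int, bend: float) -> np.ndarray:
    if n_seg < 1:
        return np.zeros(0)
    if n_seg == 1:
        return np.zeros(1)
    return np.linspace(0.0, bend, n_seg)


def build_gag(preset_name: str, dp: int = 10) -> GAGChain:
    """Build a GAG chain of one of the seven presets.

    Site counts scale linearly with dp/2; at dp = 10 they reproduce the
    reference inventories (HP 15 sulfates, deHP 0, CS4/CS6 5, HS1-3 10 each,
    always 5 carboxylates).
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown GAG preset {preset_name!r}; valid presets: "
            f"{sorted(PRESETS)}"
        )
    if not isinstance(dp, (int, np.integer)) or isinstance(dp, bool):
        raise ValueError(f"dp must be an integer, got {dp!r}")
    if dp < 2 or dp % 2 != 0:
        raise ValueError(f"dp must be an even integer >= 2, got {dp}")

    sites: list[AnionicSite] = []
    for d in range(dp // 2):
        hexosamine = 2 * d + 1
        uronic = 2 * d + 2
        for st in PRESETS[preset_name]:
            residue = hexosamine if st in _HEXOSAMINE_SULFATES else uronic
            sites.append(AnionicSite(st, residue))
        sites.append(AnionicSite("carboxylate", uronic))

    charge = -(len(PRESETS[preset_name]) + 1)
    return GAGChain(preset_name, int(dp), sites, charge)


def count_anionic_sites(chain: GAGChain) -> dict[str, int]:
    """Per-type site counts; only types present in the chain appear."""
    counts = Counter(s.site_type for s in chain.sites)
    return {st: counts[st] for st in SITE_TYPES if counts[st] > 0}


# ---------------------------------------------------------------------------
# methylene blue template
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    """Rigid-body placement: x -> x @ R.T + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ np.asarray(self.rotation).T + np.asarray(self.translation)


def _ring_lattice() -> np.ndarray:
    """Planar lattice of three edge-fused benzene-like hexagons (z = 0)."""
    apothem = _CC_BOND * np.cos(np.pi / 6.0)
    centers = np.array([-2 * apothem, 0.0, 2 * apothem])
    angles = np.deg2rad(np.arange(30, 360, 60))
    pts: list[np.ndarray] = []
    for cx in centers:
        for a in angles:
            p = np.array([cx + _CC_BOND * np.cos(a), _CC_BOND * np.sin(a), 0.0])
            if not any(np.linalg.norm(p - q) < 1e-6 for q in pts):
                pts.append(p)
    arr = np.array(pts)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


@dataclass
class MBMolecule:
    """Rigid planar methylene blue template (local coordinates, Angstrom).

    The tricycle is approximated by a 14-atom planar lattice of fused
    benzene-like rings (C-C 1.39 A) in the xy-plane; the two terminal
    dimethylamino nitrogens sit 1.35 A outside the terminal rings on the long
    (x) axis, symmetric about the centre.  Formal charge +1.
    """

    ring_atoms: np.ndarray
    terminal_nitrogens: np.ndarray
    charge: int = 1

    @classmethod
    def template(cls) -> "MBMolecule":
        rings = _ring_lattice()
        x_out = float(np.max(np.abs(rings[:, 0]))) + _N_OFFSET
        nitrogens = np.array([[-x_out, 0.0, 0.0], [x_out, 0.0, 0.0]])
        return cls(rings, nitrogens)

    @property
    def n_ring_atoms(self) -> int:
        return len(self.ring_atoms)

    @property
    def n_atoms(self) -> int:
        return self.n_ring_atoms + 2

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector terminal-N #1 -> terminal-N #2 in template frame."""
        v = self.terminal_nitrogens[1] - self.terminal_nitrogens[0]
        return v / np.linalg.norm(v)

    @property
    def all_atoms(self) -> np.ndarray:
        """Ring atoms followed by the two terminal nitrogens, (n_atoms, 3)."""
        return np.vstack([self.ring_atoms, self.terminal_nitrogens])

    def place(self, pose: Pose) -> np.ndarray:
        """All atom coordinates under a rigid pose, rings first then N1, N2."""
        return pose.apply(self.all_atoms)
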