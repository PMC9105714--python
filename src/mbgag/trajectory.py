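"""In-memory trajectory container and topology handling.

A trajectory is an ordered stack of coordinate frames for all MB molecules
and (optionally) one GAG chain, plus a flat topology table assigning every
atom a molecule id, a label, a role and, for anionic-site anchors, a site
type and residue index.  Roles:

    ring          MB aromatic ring atom (defines the stacking plane)
    terminal_N    MB terminal dimethylamino nitrogen (defines the long axis,
                  anchors electrostatic contacts)
    backbone      GAG backbone bead
    sulfate_S     sulfate sulfur anchor of an anionic site
    carboxylate_C carboxyl carbon anchor of an anionic site
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gag_models import GAGChain, MBMolecule

__all__ = ["Trajectory", "make_topology", "ROLES", "GAG_ID"]

ROLES = ("ring", "terminal_N", "backbone", "sulfate_S", "carboxylate_C")
ANCHOR_ROLES = ("sulfate_S", "carboxylate_C")
GAG_ID = "GAG"


def make_topology(
    chain: GAGChain | None,
    mb_count: int,
    template: MBMolecule | None = None,
) -> pd.DataFrame:
    """Topology table: GAG backbone beads, GAG site anchors, then MB atoms.

    MB molecules are labelled MB1..MBn, each contributing its ring atoms
    (C1..) followed by the two terminal nitrogens (N1, N2).
    """
    if template is None:
        template = MBMolecule.template()
    rows: list[dict] = []
    if chain is not None:
        for r in range(1, chain.dp + 1):
            rows.append(
                dict(molecule_id=GAG_ID, atom_label=f"B{r}", role="backbone",
                     site_type="-", residue_index=r)
            )
        for i, site in enumerate(chain.sites):
            rows.append(
                dict(molecule_id=GAG_ID, atom_label=f"S{i + 1}",
                     role=site.anchor_label, site_type=site.site_type,
                     residue_index=site.residue_index)
            )
    for m in range(1, mb_count + 1):
        mb_id = f"MB{m}"
        for c in range(1, template.n_ring_atoms + 1):
            rows.append(
                dict(molecule_id=mb_id, atom_label=f"C{c}", role="ring",
                     site_type="-", residue_index=m)
            )
        for n in (1, 2):
            rows.append(
                dict(molecule_id=mb_id, atom_label=f"N{n}", role="terminal_N",
                     site_type="-", residue_index=m)
            )
    return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Ordered coordinate frames plus the topology labelling every atom."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    topology: pd.DataFrame
    frame_interval: float = 1.0

    _ring_idx: dict[str, np.ndarray] = field(init=False, repr=False)
    _n_idx: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} rows but frames carry "
                f"{self.coords.shape[1]} atoms"
            )
        bad = set(self.topology["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown topology role labels: {sorted(bad)}")
        top = self.topology
        self._ring_idx = {}
        self._n_idx = {}
        for mb_id in self.mb_ids:
            mol = top["molecule_id"] == mb_id
            self._ring_idx[mb_id] = np.flatnonzero(mol & (top["role"] == "ring"))
            self._n_idx[mb_id] = np.flatnonzero(mol & (top["role"] == "terminal_N"))
            if len(self._n_idx[mb_id]) != 2:
                raise ValueError(f"{mb_id} must have exactly 2 terminal_N atoms")
            if len(self._ring_idx[mb_id]) < 3:
                raise ValueError(f"{mb_id} must have at least 3 ring atoms")

    # ---- shape ----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def mb_ids(self) -> list[str]:
        seen: list[str] = []
        for mid in self.topology["molecule_id"]:
            if mid != GAG_ID and mid not in seen:
                seen.append(mid)
        return seen

    @property
    def mb_count(self) -> int:
        return len(self.mb_ids)

    @property
    def has_gag(self) -> bool:
        return bool((self.topology["molecule_id"] == GAG_ID).any())

    # ---- selections -----------------------------------------------------

    def ring_coords(self, frame: int, mb_id: str) -> np.ndarray:
        return self.coords[frame, self._ring_idx[mb_id]]

    def terminal_n_coords(self, frame: int, mb_id: str) -> np.ndarray:
        return self.coords[frame, self._n_idx[mb_id]]

    @property
    def backbone_indices(self) -> np.ndarray:
        return np.flatnonzero(self.topology["role"] == "backbone")

    @property
    def site_table(self) -> pd.DataFrame:
        """Anchor atoms: columns atom_index, site_type, residue_index."""
        mask = self.topology["role"].isin(ANCHOR_ROLES)
        tab = self.topology.loc[mask, ["site_type", "residue_index"]].copy()
        tab.insert(0, "atom_index", np.flatnonzero(mask))
        return tab.reset_index(drop=True)

    def terminal_n_indices(self) -> np.ndarray:
        """(mb_count, 2) atom indices of terminal nitrogens, in mb_ids order."""
        return np.array([self._n_idx[m] for m in self.mb_ids])
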