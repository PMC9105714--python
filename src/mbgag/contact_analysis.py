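"""MB-GAG distance time series, contact fractions and binder counts.

The contact observable follows the dye's electrostatics: the distance
between an MB molecule and an anionic site is the minimum over the two
terminal dimethylamino nitrogens of the Euclidean distance to the site's
anchor atom (sulfate sulfur or carboxyl carbon).  A pair is "in contact"
in a frame when that distance is strictly below the cutoff (default 8 A).

Per site type the primary report is the percentage of frames in which at
least one (MB, site) pair of that type is in contact; the per-pair mean
occupancy is emitted alongside as a secondary reading.  A molecule counts
as bound when it contacts any site of any type, and the number of
simultaneously bound molecules per frame feeds the sulfation-dependence
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gag_models import GAGChain, SITE_TYPES, count_anionic_sites
from .trajectory import Trajectory

__all__ = [
    "ContactTable",
    "BindingSummary",
    "mb_site_distance",
    "distance_tensor",
    "contact_fractions",
    "binding_summary",
    "chain_bending",
]

CUTOFF = 8.0  # contact cutoff, Angstrom


def mb_site_distance(n_coords: np.ndarray, anchor: np.ndarray) -> float:
    """Min over the two terminal nitrogens of the distance to the anchor."""
    n_coords = np.asarray(n_coords, float).reshape(2, 3)
    anchor = np.asarray(anchor, float).reshape(3)
    return float(np.min(np.linalg.norm(n_coords - anchor, axis=1)))


def _check_chain(traj: Trajectory, chain: GAGChain | None) -> None:
    if not traj.has_gag:
        raise ValueError("trajectory carries no GAG chain")
    if chain is not None:
        top_counts = traj.site_table["site_type"].value_counts().to_dict()
        if top_counts != count_anionic_sites(chain):
            raise ValueError(
                "trajectory topology and chain disagree on anionic-site "
                f"inventories: {top_counts} vs {count_anionic_sites(chain)}"
            )


def distance_tensor(traj: Trajectory) -> tuple[np.ndarray, list[str]]:
    """MB-site distances, shape (n_frames, mb_count, n_sites).

    Entry [f, m, s] is the min-over-nitrogens distance of molecule m to
    anchor s in frame f; the second return value lists the site types in
    anchor order.
    """
    sites = traj.site_table
    if len(sites) == 0:
        raise ValueError("trajectory topology contains no anionic sites")
    anchor_xyz = traj.coords[:, sites["atom_index"].to_numpy()]  # (F, S, 3)
    n_idx = traj.terminal_n_indices()  # (M, 2)
    n_xyz = traj.coords[:, n_idx]  # (F, M, 2, 3)
    diff = n_xyz[:, :, :, None, :] - anchor_xyz[:, None, None, :, :]
    dist = np.linalg.norm(diff, axis=-1).min(axis=2)  # (F, M, S)
    return dist, list(sites["site_type"])


@dataclass
class ContactTable:
    """Contact-fraction report for one trajectory/chain.

    ``fractions`` maps each site type present in the chain to the
    percentage of frames with at least one sub-cutoff pair of that type;
    absent types simply do not appear (rendered "-" in tabular output).
    """

    fractions: dict[str, float]  # percent, any-pair-per-frame reading
    pair_mean_occupancy: dict[str, float]  # percent, per-pair mean reading
    bound_flags: np.ndarray  # (n_frames, mb_count) bool
    bound_counts: np.ndarray  # (n_frames,) int
    mb_ids: list[str]
    cutoff: float

    def fraction_or_none(self, site_type: str) -> float | None:
        return self.fractions.get(site_type)

    @property
    def count_distribution(self) -> dict[int, float]:
        counts = np.bincount(self.bound_counts, minlength=len(self.mb_ids) + 1)
        total = len(self.bound_counts)
        return {k: c / total for k, c in enumerate(counts)}


def contact_fractions(
    traj: Trajectory, chain: GAGChain | None = None, cutoff: float = CUTOFF
) -> ContactTable:
    """Per-site-type contact time fractions (percent) plus bound flags."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    _check_chain(traj, chain)
    dist, types = distance_tensor(traj)
    in_contact = dist < cutoff  # strict: "below" the cutoff
    types_arr = np.array(types)
    fractions: dict[str, float] = {}
    pair_mean: dict[str, float] = {}
    for st in SITE_TYPES:
        mask = types_arr == st
        if not mask.any():
            continue
        sub = in_contact[:, :, mask]  # (F, M, S_t)
        fractions[st] = 100.0 * float(sub.any(axis=(1, 2)).mean())
        pair_mean[st] = 100.0 * float(sub.mean())
    bound_flags = in_contact.any(axis=2)
    return ContactTable(
        fractions=fractions,
        pair_mean_occupancy=pair_mean,
        bound_flags=bound_flags,
        bound_counts=bound_flags.sum(axis=1).astype(int),
        mb_ids=traj.mb_ids,
        cutoff=cutoff,
    )


@dataclass
class BindingSummary:
    """Simultaneous-binder summary.

    n_mb is the maximum number of molecules bound at once; t the fraction
    of frames at (>=) that count.  Because the reading of the published
    convention is not unique, the full count distribution is kept.
    """

    n_mb: int
    t: float
    count_distribution: dict[int, float]

    @property
    def no_binding(self) -> bool:
        return self.n_mb == 0


def binding_summary(
    traj: Trajectory, chain: GAGChain | None = None, cutoff: float = CUTOFF
) -> BindingSummary:
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    table = contact_fractions(traj, chain, cutoff)
    counts = table.bound_counts
    n_mb = int(counts.max())
    t = float(np.mean(counts >= n_mb))
    return BindingSummary(n_mb=n_mb, t=t,
                          count_distribution=table.count_distribution)


def chain_bending(traj: Trajectory) -> np.ndarray:
    """Per-frame end-to-end over contour-length ratio of the GAG backbone.

    1.0 for a fully extended chain; smaller for bent conformations.
    """
    idx = traj.backbone_indices
    if len(idx) < 2:
        raise ValueError("chain needs at least 2 backbone beads")
    beads = traj.coords[:, idx]  # (F, B, 3)
    end_to_end = np.linalg.norm(beads[:, -1] - beads[:, 0], axis=1)
    contour = np.linalg.norm(np.diff(beads, axis=1), axis=2).sum(axis=1)
    return end_to_end / contour
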