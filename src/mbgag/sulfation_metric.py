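"""The sulfation-dependence statistic D.

D = n_MB * t / n_SO3, where n_MB is the number of MB molecules bound to the
GAG simultaneously, t the fraction of simulation time spent at that count,
and n_SO3 the number of sulfate groups on the chain.  D normalizes the
binding occupancy by the sulfation level; it is undefined for a desulfated
chain (n_SO3 = 0).  Reported values are rounded half away from zero to two
decimals; the raw value is retained for chaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .contact_analysis import BindingSummary
from .gag_models import GAGChain

__all__ = ["DResult", "compute_D", "d_table", "round_half_away"]


def round_half_away(x: float, ndigits: int) -> float:
    """Round with exact halves going away from zero (-5.55 -> -5.6)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DResult:
    n_mb: int
    n_so3: int
    t: float
    value: float | None  # raw; None when undefined (n_so3 = 0)
    rounded: float | None  # reporting value, 2 decimals

    @property
    def defined(self) -> bool:
        return self.value is not None


def compute_D(n_mb: int, t: float, n_so3: int) -> DResult:
    """Evaluate D = n_MB * t / n_SO3; undefined when n_SO3 = 0."""
    if n_mb < 0:
        raise ValueError("n_mb must be >= 0")
    if n_so3 < 0:
        raise ValueError("n_so3 must be >= 0")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    if n_so3 == 0:
        return DResult(n_mb, n_so3, t, None, None)
    value = n_mb * t / n_so3
    return DResult(n_mb, n_so3, t, value, round_half_away(value, 2))


def d_table(
    summaries: list[tuple[str, BindingSummary]],
    chains: dict[str, GAGChain],
) -> pd.DataFrame:
    """One row per preset: gag, n_MB, n_SO3, t, D ("-" where undefined)."""
    presets = [p for p, _ in summaries]
    if len(set(presets)) != len(presets):
        raise ValueError("presets must be unique")
    rows = []
    for preset, summary in summaries:
        chain = chains[preset]
        res = compute_D(summary.n_mb, summary.t, chain.n_sulfates)
        rows.append(
            dict(
                gag=preset,
                n_MB=summary.n_mb,
                n_SO3=chain.n_sulfates,
                t="-" if res.n_so3 == 0 else round_half_away(summary.t, 2),
                D="-" if not res.defined else f"{res.rounded:.2f}",
            )
        )
    return pd.DataFrame(rows)
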