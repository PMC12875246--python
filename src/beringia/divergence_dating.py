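"""Divergence dating from genetic distances with order-calibrated rates.

Rates are expressed as PAIRWISE percent divergence per million years (both
lineages accumulating substitutions), so a date is simply t = d / rate with no
extra factor of two. Passerine-calibrated base rates are rescaled to other
avian orders by the ratio of order-level rates:

    scaled = base × (rate_order / rate_passeriformes)

A pair whose order has no table entry fails loudly; silent fallback to the
passerine rate would miscalibrate exactly the taxa the scaling exists for.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigError, InputError
from .io_manifest import PASSERINE_ORDER


def scale_rate(
    base_rate: float, arcones_lineage: float, arcones_passeriformes: float
) -> float:
    """Rescale a passerine-calibrated rate to another order.

    All arguments are in % pairwise divergence per Myr and must be positive.
    """
    for label, val in (
        ("base_rate", base_rate),
        ("order rate", arcones_lineage),
        ("passerine rate", arcones_passeriformes),
    ):
        if val <= 0:
            raise InputError(f"{label} must be positive, got {val}")
    return base_rate * (arcones_lineage / arcones_passeriformes)


def date_from_distance(d: float, rate: float) -> float:
    """Divergence time in Myr from a % distance and a % per-Myr pairwise rate."""
    if rate <= 0:
        raise ConfigError(f"divergence rate must be positive, got {rate}")
    if d < 0:
        raise InputError(f"distance must be >= 0, got {d}")
    return d / rate


def lookup_rate(rate_table: pd.DataFrame, order: str, locus: str) -> float:
    """Rate for (order, locus) from a table read by io_manifest.read_rate_table."""
    try:
        return float(rate_table.loc[(order, locus), "rate"])
    except KeyError:
        raise ConfigError(
            f"no divergence rate for order {order!r}, locus {locus!r}; "
            "add it to the rate table (no silent passerine fallback)"
        ) from None


def scaled_rate_for(
    rate_table: pd.DataFrame, base_rate: float, order: str, locus: str
) -> float:
    """Passerine base rate rescaled to ``order`` using the table's ordinal rates."""
    lineage = lookup_rate(rate_table, order, locus)
    passerine = lookup_rate(rate_table, PASSERINE_ORDER, locus)
    return scale_rate(base_rate, lineage, passerine)


def date_pairs(
    distances_pct: pd.Series, orders: pd.Series, loci: pd.Series, rate_table: pd.DataFrame
) -> pd.Series:
    """Vector of dates (Myr) for per-pair % distances with per-pair (order, locus)."""
    dates = []
    for d, order, locus in zip(distances_pct, orders, loci):
        rate = lookup_rate(rate_table, order, locus)
        dates.append(date_from_distance(d, rate))
    return pd.Series(dates, index=distances_pct.index, name="date_mya")
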