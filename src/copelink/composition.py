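"""Filtering of plankton-abundance records and copepod order composition.

Public plankton databases (COPEPOD, NRS-IMOS) mix depths, mesh sizes and
life stages.  Coarse nets (200 µm) undersample small copepods, and
nauplii are not the life stage that preys on metazoans, so the
composition used for the global budget keeps only adults and copepodites
caught above 100 m with a fine mesh (100–116 µm).  From the filtered
records we compute the abundance-weighted share of each copepod order
per realm (coastal vs oceanic); poecilostomatoids are carnivores
traditionally placed within the cyclopoids and are merged with them for
budget purposes, while harpacticoids are reported but excluded from the
calanoid/cyclopoid split without renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ORDERS = ("calanoid", "cyclopoid", "harpacticoid", "poecilostomatoid", "other")
STAGES = ("adult", "copepodite", "nauplius")
REALMS = ("coastal", "oceanic")

#: Columns of an abundance-record table, in canonical order.
ABUNDANCE_COLUMNS = [
    "station_id",
    "realm",
    "depth_m",
    "mesh_um",
    "order",
    "stage",
    "abundance",
]


@dataclass(frozen=True)
class CompositionProfile:
    """Copepod order composition of one realm.

    Proportions are shares of total (filtered) abundance.  The effective
    cyclopoid share merges poecilostomatoids into cyclopoids; the
    harpacticoid share is carried for reporting but is not redistributed
    over the remaining orders.
    """

    realm: str
    p_cal: float
    p_cyc: float
    p_har: float = 0.0
    p_poe: float = 0.0
    n_records_used: int = 0

    @property
    def p_cyc_effective(self) -> float:
        """Cyclopoid share with poecilostomatoids merged in."""
        return self.p_cyc + self.p_poe

    def __post_init__(self) -> None:
        for name in ("p_cal", "p_cyc", "p_har", "p_poe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.p_cal + self.p_cyc + self.p_har + self.p_poe
        if total > 1.0 + 1e-9:
            raise ValueError(f"order proportions sum to {total} > 1")
        if self.realm not in REALMS:
            raise ValueError(f"unknown realm {self.realm!r}")


#: Composition of the coastal realm (NRS-IMOS stations, continental shelf).
COASTAL_PROFILE = CompositionProfile(
    realm="coastal", p_cal=0.605, p_cyc=0.285, p_har=0.0, p_poe=0.11
)

#: Composition of the oceanic realm (COPEPOD database, global coverage).
OCEANIC_PROFILE = CompositionProfile(
    realm="oceanic", p_cal=0.913, p_cyc=0.059, p_har=0.024, p_poe=0.004
)


def filter_records(
    records: pd.DataFrame,
    max_depth_m: float = 100.0,
    mesh_range_um: tuple[float, float] = (100.0, 116.0),
    stages: frozenset[str] | set[str] = frozenset({"adult", "copepodite"}),
) -> pd.DataFrame:
    """Keep abundance records usable for the composition estimate.

    A record is retained when its depth is at or above ``max_depth_m``,
    its mesh size lies inside ``mesh_range_um`` (both ends inclusive)
    and its life stage is in ``stages``.  Row order is preserved; an
    empty result is legal.
    """
    lo, hi = mesh_range_um
    keep = (
        (records["depth_m"] <= max_depth_m)
        & (records["mesh_um"] >= lo)
        & (records["mesh_um"] <= hi)
        & records["stage"].isin(stages)
    )
    return records.loc[keep]


def composition_profile(
    filtered: pd.DataFrame,
    realm: str,
    weighting: str = "abundance",
) -> CompositionProfile:
    """Abundance-weighted order composition of a filtered record set.

    Parameters
    ----------
    filtered
        Records for a single realm, already passed through
        :func:`filter_records`.
    realm
        ``"coastal"`` or ``"oceanic"``; stored on the profile.
    weighting
        ``"abundance"`` (default) weights each record by its abundance
        value, matching databases that report densities;
        ``"record_count"`` gives every record equal weight, for
        sensitivity analysis.

    Raises
    ------
    ValueError
        If ``filtered`` is empty (a profile of nothing is undefined).
    """
    if len(filtered) == 0:
        raise ValueError("cannot compute a composition profile from zero records")
    if weighting not in ("abundance", "record_count"):
        raise ValueError(f"unknown weighting {weighting!r}")

    if weighting == "abundance":
        weights = filtered.groupby("order")["abundance"].sum()
    else:
        weights = filtered.groupby("order")["abundance"].size().astype(float)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("total abundance is zero; profile undefined")
    share = weights / total
    return CompositionProfile(
        realm=realm,
        p_cal=float(share.get("calanoid", 0.0)),
        p_cyc=float(share.get("cyclopoid", 0.0)),
        p_har=float(share.get("harpacticoid", 0.0)),
        p_poe=float(share.get("poecilostomatoid", 0.0)),
        n_records_used=int(len(filtered)),
    )


def read_abundance_csv(path: str | Path) -> pd.DataFrame:
    """Strict-schema reader for abundance-record CSV files.

    Validates column presence, categorical values and numeric ranges,
    reporting the (1-based, header-inclusive) row numbers of malformed
    records so they can be fixed at the source.
    """
    df = pd.read_csv(path)
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    problems: list[str] = []

    def _flag(mask: pd.Series, message: str) -> None:
        rows = (df.index[mask] + 2).tolist()  # +2: header + 1-based
        if rows:
            problems.append(f"{message} (rows {rows[:10]}{'…' if len(rows) > 10 else ''})")

    _flag(~df["order"].isin(ORDERS), "unknown order label")
    _flag(~df["stage"].isin(STAGES), "unknown stage label")
    _flag(~df["realm"].isin(REALMS), "unknown realm label")
    _flag(pd.to_numeric(df["abundance"], errors="coerce").fillna(-1) < 0, "negative or non-numeric abundance")
    _flag(pd.to_numeric(df["depth_m"], errors="coerce").fillna(-1) < 0, "negative or non-numeric depth_m")
    _flag(pd.to_numeric(df["mesh_um"], errors="coerce").fillna(0) <= 0, "non-positive mesh_um")
    if problems:
        raise ValueError(f"{path}: malformed records: " + "; ".join(problems))
    return df[ABUNDANCE_COLUMNS + [c for c in df.columns if c not in ABUNDANCE_COLUMNS]]
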