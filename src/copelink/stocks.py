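"""Global adult copepod standing stocks in the top 100 m.

The global mesozooplankton stock in the upper 100 m (0.31 GtC) is
corrected upward by one third for the undersampling of 200-µm nets,
multiplied by the copepod share of zooplankton biomass (80%) and by the
adult + older-copepodite share of copepods (60%), giving the adult
copepod stock:

    B_adult = z0 * (1 + 1/3) * 0.8 * 0.6 = 0.1984 GtC

That stock is then split into calanoids and cyclopoids using a realm
composition profile.  Two cyclopoid conventions exist: ``merged`` counts
poecilostomatoids as cyclopoids (the budget's default), ``strict`` uses
the cyclopoid share alone.  The harpacticoid share is dropped, not
redistributed, so group stocks sum to less than the adult total.
"""

from __future__ import annotations

from dataclasses import dataclass

from copelink.composition import CompositionProfile


@dataclass(frozen=True)
class StockParams:
    """Scalars of the standing-stock correction chain (defaults published).

    z0_GtC
        Global mesozooplankton standing stock in the top 100 m, GtC.
    net_correction
        Additive fraction correcting 200-µm-net undersampling (1/3).
    f_copepod
        Copepod share of zooplankton biomass (0.8).
    f_adult
        Adult + older copepodite share of copepods (0.6).
    """

    z0_GtC: float = 0.31
    net_correction: float = 1.0 / 3.0
    f_copepod: float = 0.8
    f_adult: float = 0.6

    def __post_init__(self) -> None:
        for name in ("z0_GtC", "net_correction", "f_copepod", "f_adult"):
            v = getattr(self, name)
            if not 0.0 < v < 2.0:
                raise ValueError(f"{name}={v} outside (0, 2)")


@dataclass(frozen=True)
class StandingStock:
    """Adult copepod carbon stock of one realm, split by group (GtC)."""

    realm: str
    B_adult_GtC: float
    B_cal_GtC: float
    B_cyc_GtC: float

    def __post_init__(self) -> None:
        if min(self.B_adult_GtC, self.B_cal_GtC, self.B_cyc_GtC) < 0:
            raise ValueError("standing stocks must be non-negative")
        if self.B_cal_GtC + self.B_cyc_GtC > self.B_adult_GtC + 1e-12:
            raise ValueError("group stocks exceed the adult total")


def adult_stock(params: StockParams = StockParams()) -> float:
    """Adult copepod standing stock, GtC in the top 100 m."""
    return params.z0_GtC * (1.0 + params.net_correction) * params.f_copepod * params.f_adult


def partition_stock(
    B_adult_GtC: float,
    profile: CompositionProfile,
    cyclopoid_mode: str = "merged",
) -> StandingStock:
    """Split the adult copepod stock into calanoids and cyclopoids.

    ``cyclopoid_mode="merged"`` uses the effective cyclopoid share
    (cyclopoids + poecilostomatoids); ``"strict"`` uses the cyclopoid
    share alone.  Harpacticoids are excluded without renormalisation.
    """
    if B_adult_GtC < 0:
        raise ValueError("adult stock must be non-negative")
    if cyclopoid_mode == "merged":
        p_cyc = profile.p_cyc_effective
    elif cyclopoid_mode == "strict":
        p_cyc = profile.p_cyc
    else:
        raise ValueError(f"unknown cyclopoid_mode {cyclopoid_mode!r}")
    return StandingStock(
        realm=profile.realm,
        B_adult_GtC=B_adult_GtC,
        B_cal_GtC=B_adult_GtC * profile.p_cal,
        B_cyc_GtC=B_adult_GtC * p_cyc,
    )
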