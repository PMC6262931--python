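"""Steady-state C and N flux ledger of the upper-ocean copepod node.

Copepod physiology is closed with a standard rate triple: assimilation
efficiency AE = 0.7, gross growth efficiency GGE = 0.3, ingestion =
2.5 x respiration (hence respiration = 0.4 x ingestion) and growth =
0.75 x respiration.  These are mutually consistent
(0.3 = 0.75 / 2.5) and partition ingested carbon exactly:

    growth (0.3 I) + respiration (0.4 I) + egestion (0.3 I) = I

Nitrogen enters via prey-specific C:N ratios (phytoplankton 6.6,
ciliates 5.0, metazoan prey and zooplankton 6.86); of ingested N, ~20%
is excreted as NH4+ and ~40% released in debris and fecal pellets.
The N ledger does not force closure — the published 20% + 40% + growth
components need not sum to ingested N, so a residual line is carried.

Downstream exports follow the COBALT model conventions: 8% of copepod
production to higher trophic levels (fisheries), 8% to remineralization,
3%–5% to dissolved organic matter; carbon sinking is 3% of egestion.

The metazoan-copepod link enters as an interval [low, high] of annual
ingestion (field scenarios), added to the unicellular baseline of 8.67
GtC/yr of phytoplankton plus 2.82 GtC/yr of ciliates.  Every
metazoan-driven flux is interval-valued; unicellular fluxes are points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: Default copepod ingestion of unicellular prey, GtC/yr (phyto, ciliates).
I_PHYTO_DEFAULT = 8.67
I_CILIATE_DEFAULT = 2.82


@dataclass(frozen=True)
class Interval:
    """A closed interval [lo, hi]; used for link-dependent fluxes."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi + 1e-12:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper {self.hi}")

    def scale(self, k: float) -> "Interval":
        return Interval(self.lo * k, self.hi * k)

    def shift(self, c: float) -> "Interval":
        return Interval(self.lo + c, self.hi + c)

    def map(self, f) -> "Interval":
        a, b = f(self.lo), f(self.hi)
        return Interval(min(a, b), max(a, b))

    def as_tuple(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass(frozen=True)
class BudgetParams:
    """Scalar parameters of the C/N budget (defaults as published).

    ``PP_GtC_per_yr`` is the primary-production denominator of the
    headline percentages.  The published source figure (45 GtC) is a
    phytoplankton standing stock, but the printed percentages back-solve
    to a 45 GtC/yr flux denominator, so it is treated as annual PP here
    and flagged in reports.
    """

    PP_GtC_per_yr: float = 45.0
    I_phyto_GtC: float = I_PHYTO_DEFAULT
    I_ciliate_GtC: float = I_CILIATE_DEFAULT
    AE: float = 0.7
    GGE: float = 0.3
    ingestion_to_respiration: float = 2.5
    growth_to_respiration: float = 0.75
    f_NH4: float = 0.2
    f_debris: float = 0.4
    CN_zoo: float = 6.86
    CN_phyto: float = 6.6
    CN_ciliate: float = 5.0
    f_HTL: float = 0.08
    f_remin: float = 0.08
    f_DOM: tuple[float, float] = (0.03, 0.05)
    f_sink_of_egestion: float = 0.03
    export_base: str = "growth"  # flux against which HTL/remin/DOM fractions apply

    def __post_init__(self) -> None:
        for name in ("AE", "GGE", "f_NH4", "f_debris", "f_HTL", "f_remin",
                     "f_sink_of_egestion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.f_DOM[0] <= self.f_DOM[1] <= 1.0:
            raise ValueError(f"f_DOM={self.f_DOM} is not an interval within [0, 1]")
        if self.export_base not in ("growth", "ingestion"):
            raise ValueError(f"unknown export_base {self.export_base!r}")
        implied_gge = self.growth_to_respiration / self.ingestion_to_respiration
        if abs(implied_gge - self.GGE) > 1e-9:
            warnings.warn(
                f"inconsistent rate triple: growth/respiration ratio implies "
                f"GGE={implied_gge:.4f} but GGE={self.GGE}; carbon will not "
                f"close exactly at the copepod node",
                stacklevel=3,
            )

    @property
    def cn_by_source(self) -> dict[str, float]:
        return {
            "phytoplankton": self.CN_phyto,
            "ciliate": self.CN_ciliate,
            "metazoan": self.CN_zoo,
        }


def close_physiology(I_total_C: float, params: BudgetParams = BudgetParams()) -> dict[str, float]:
    """Partition ingested carbon at the copepod node (GtC/yr).

    Returns the full C ledger: assimilation = AE*I, growth = GGE*I,
    respiration = I / (I:R ratio), egestion = (1-AE)*I, sinking =
    3% of egestion.  With the consistent default triple the three loss
    terms sum to ingestion at machine precision.
    """
    if I_total_C < 0:
        raise ValueError("ingestion must be non-negative")
    egestion = (1.0 - params.AE) * I_total_C
    return {
        "ingestion": I_total_C,
        "assimilation": params.AE * I_total_C,
        "growth": params.GGE * I_total_C,
        "respiration": I_total_C / params.ingestion_to_respiration,
        "egestion": egestion,
        "sinking": params.f_sink_of_egestion * egestion,
    }


def nitrogen_ledger(
    I_by_source: dict[str, float],
    params: BudgetParams = BudgetParams(),
) -> dict[str, float]:
    """Nitrogen ledger of the copepod node (GtN/yr).

    Each carbon source is converted with its C:N ratio; NH4+ excretion
    and debris/pellet release are fixed fractions of total ingested N;
    growth N uses the zooplankton C:N.  Closure is not forced: the
    residual (ingested - NH4 - debris - growth) is reported as is.
    """
    cn = params.cn_by_source
    unknown = [s for s in I_by_source if s not in cn]
    if unknown:
        raise ValueError(f"no C:N ratio for source(s) {unknown}")
    n_by_source = {s: I / cn[s] for s, I in I_by_source.items()}
    n_total = sum(n_by_source.values())
    c_total = sum(I_by_source.values())
    growth_n = params.GGE * c_total / params.CN_zoo
    ledger = {f"ingested_N[{s}]": n for s, n in n_by_source.items()}
    ledger.update(
        {
            "ingested_N_total": n_total,
            "NH4_N": params.f_NH4 * n_total,
            "debris_N": params.f_debris * n_total,
            "growth_N": growth_n,
            "residual_N": n_total * (1.0 - params.f_NH4 - params.f_debris) - growth_n,
        }
    )
    return ledger


def headline_metrics(I_met: float, params: BudgetParams = BudgetParams()) -> dict[str, float]:
    """Headline percentages for a metazoan-link ingestion of ``I_met`` GtC/yr.

    * ``pct_of_PP`` — the link as a share of primary production.
    * ``pct_increment_over_unicellular`` — the relative increase over
      the combined phytoplankton + ciliate ingestion; this is the
      increment available to copepod growth, pellet production, export
      and transfer to higher trophic levels.
    * ``pct_PP_indirect`` — share of PP reaching copepods indirectly,
      assuming metazoan prey are single-trophic-level grazers with prey
      gross efficiency AE*GGE (= 0.21): prey consume I_met / (AE*GGE)
      of PP to sustain the link.
    """
    if I_met < 0:
        raise ValueError("link ingestion must be non-negative")
    if params.PP_GtC_per_yr <= 0:
        raise ValueError("primary production must be positive")
    unicellular = params.I_phyto_GtC + params.I_ciliate_GtC
    if unicellular <= 0:
        raise ValueError("unicellular ingestion must be positive")
    prey_efficiency = params.AE * params.GGE
    return {
        "pct_of_PP": 100.0 * I_met / params.PP_GtC_per_yr,
        "pct_increment_over_unicellular": 100.0 * I_met / unicellular,
        "pct_PP_indirect": 100.0 * (I_met / prey_efficiency) / params.PP_GtC_per_yr,
    }


def nitrogen_regeneration_ratio(I_met: float, params: BudgetParams = BudgetParams()) -> float:
    """Factor by which the link raises regenerated N available to PP.

    Regenerated N (NH4+ plus pellet/debris release, 60% of ingested N
    under the default fractions) scales with total ingested N, so the
    ratio with-link : baseline reduces to a ratio of ingested N and the
    regenerated fraction cancels.
    """
    base_n = params.I_phyto_GtC / params.CN_phyto + params.I_ciliate_GtC / params.CN_ciliate
    if base_n <= 0:
        raise ValueError("baseline ingested N must be positive")
    return (base_n + I_met / params.CN_zoo) / base_n


@dataclass(frozen=True)
class FluxBudget:
    """Interval-valued C/N ledger of the copepod node with the link.

    Metazoan-driven quantities are :class:`Interval`; unicellular
    baseline fluxes are point values.  All carbon in GtC/yr, nitrogen
    in GtN/yr.
    """

    params: BudgetParams
    I_met: Interval
    I_by_source: dict[str, object]           # point floats + metazoan Interval
    carbon: dict[str, Interval]              # total-node C ledger
    nitrogen: dict[str, object]              # N ledger (points + Intervals)
    exports: dict[str, Interval]             # HTL, remineralization, DOM, sinking
    headline: dict[str, Interval]            # derived percentages

    def edge_table(self) -> list[dict[str, object]]:
        """Node/edge rows suitable for CSV/JSON export or graph rendering."""

        def _fmt(v):
            return v.as_tuple() if isinstance(v, Interval) else (v, v)

        edges = [
            ("primary_production", "copepods", "C", _fmt(self.I_by_source["phytoplankton"])),
            ("ciliates", "copepods", "C", _fmt(self.I_by_source["ciliate"])),
            ("metazoan_prey", "copepods", "C", _fmt(self.I_by_source["metazoan"])),
            ("copepods", "copepod_growth", "C", _fmt(self.carbon["growth"])),
            ("copepods", "respiration", "C", _fmt(self.carbon["respiration"])),
            ("copepods", "egestion", "C", _fmt(self.carbon["egestion"])),
            ("egestion", "sinking_export", "C", _fmt(self.exports["sinking"])),
            ("copepods", "HTL", "C", _fmt(self.exports["HTL"])),
            ("copepods", "remineralization", "C", _fmt(self.exports["remineralization"])),
            ("copepods", "DOM", "C", _fmt(self.exports["DOM"])),
            ("copepods", "NH4_pool", "N", _fmt(self.nitrogen["NH4_N"])),
            ("copepods", "debris_N_pool", "N", _fmt(self.nitrogen["debris_N"])),
        ]
        return [
            {"source": s, "target": t, "currency": c, "low": lo, "high": hi}
            for (s, t, c, (lo, hi)) in edges
        ]

    def to_dot(self) -> str:
        """GraphViz DOT dump of the budget (edges labelled lo–hi GtC/yr)."""
        lines = ["digraph flux_budget {", "  rankdir=LR;"]
        for row in self.edge_table():
            lo, hi = row["low"], row["high"]
            label = f"{lo:.3g}" if abs(hi - lo) < 1e-12 else f"{lo:.3g}–{hi:.3g}"
            unit = "GtC/yr" if row["currency"] == "C" else "GtN/yr"
            lines.append(
                f'  "{row["source"]}" -> "{row["target"]}" [label="{label} {unit}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def assemble_budget(
    I_met_low: float,
    I_met_high: float,
    params: BudgetParams = BudgetParams(),
) -> FluxBudget:
    """Build the interval-valued flux budget for a link range [low, high]."""
    if I_met_low > I_met_high:
        raise ValueError(f"low scenario {I_met_low} exceeds high {I_met_high}")
    if I_met_low < 0:
        raise ValueError("link ingestion must be non-negative")

    link = Interval(I_met_low, I_met_high)
    unicellular = params.I_phyto_GtC + params.I_ciliate_GtC

    def _interval(f) -> Interval:
        return Interval(f(link.lo), f(link.hi))

    total_I = link.shift(unicellular)
    carbon = {
        key: _interval(lambda x, k=key: close_physiology(x + unicellular, params)[k])
        for key in ("ingestion", "assimilation", "growth", "respiration", "egestion")
    }

    def _nitrogen(x: float) -> dict[str, float]:
        return nitrogen_ledger(
            {
                "phytoplankton": params.I_phyto_GtC,
                "ciliate": params.I_ciliate_GtC,
                "metazoan": x,
            },
            params,
        )

    n_keys = _nitrogen(link.lo).keys()
    nitrogen: dict[str, object] = {
        k: Interval(_nitrogen(link.lo)[k], _nitrogen(link.hi)[k])
        if _nitrogen(link.hi)[k] >= _nitrogen(link.lo)[k]
        else Interval(_nitrogen(link.hi)[k], _nitrogen(link.lo)[k])
        for k in n_keys
    }

    base = carbon["growth"] if params.export_base == "growth" else carbon["ingestion"]
    exports = {
        "HTL": base.scale(params.f_HTL),
        "remineralization": base.scale(params.f_remin),
        "DOM": Interval(base.lo * params.f_DOM[0], base.hi * params.f_DOM[1]),
        "sinking": carbon["egestion"].scale(params.f_sink_of_egestion),
    }

    hm_lo, hm_hi = headline_metrics(link.lo, params), headline_metrics(link.hi, params)
    headline = {k: Interval(hm_lo[k], hm_hi[k]) for k in hm_lo}
    headline["N_regeneration_ratio"] = Interval(
        nitrogen_regeneration_ratio(link.lo, params),
        nitrogen_regeneration_ratio(link.hi, params),
    )

    return FluxBudget(
        params=params,
        I_met=link,
        I_by_source={
            "phytoplankton": params.I_phyto_GtC,
            "ciliate": params.I_ciliate_GtC,
            "metazoan": link,
        },
        carbon=carbon,
        nitrogen=nitrogen,
        exports=exports,
        headline=headline,
    )
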