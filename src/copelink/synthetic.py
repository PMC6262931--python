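"""Synthetic input generators with planted ground truth.

Three input families feed the pipeline: plankton-abundance tables,
ingestion-rate meta-analysis tables, and gut-content clone libraries.
Each generator emulates the corresponding real data source closely
enough to exercise every downstream filter and estimator, and returns
the planted truth so recovery can be asserted exactly.

All draws come from one :class:`numpy.random.Generator` seeded per
spec — identical spec + seed gives byte-identical output, and no global
random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copelink.gut import CloneSequence

#: Fraction of abundance records deliberately violating the composition
#: filters (too deep, coarse mesh, or naupliar stage) so that filter
#: tests are non-vacuous.
DECOY_RATE = 0.2

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# abundance records


@dataclass(frozen=True)
class SyntheticAbundanceSpec:
    """Recipe for a plankton-abundance table with known composition.

    ``true_fractions`` is the order composition that filtered records
    converge to; decoy records (violating depth, mesh or stage filters)
    are injected at a fixed 20% rate and flagged in a ``decoy`` column.
    """

    realm_label: str
    n_records: int
    true_fractions: dict[str, float]
    depth_range_m: tuple[float, float] = (0.0, 100.0)
    mesh_values_um: tuple[float, ...] = (100.0, 110.0, 116.0, 200.0, 333.0)
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {"adult": 0.6, "copepodite": 0.3, "nauplius": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError(f"n_records={self.n_records} must be positive")
        total = sum(self.true_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"true_fractions sum to {total}, not 1")
        if any(v < 0 for v in self.true_fractions.values()):
            raise ValueError("true_fractions must be non-negative")
        if self.depth_range_m[0] > self.depth_range_m[1] or self.depth_range_m[0] < 0:
            raise ValueError(f"invalid depth_range_m {self.depth_range_m}")
        if not self.mesh_values_um:
            raise ValueError("mesh_values_um must be non-empty")
        if abs(sum(self.stage_mix.values()) - 1.0) > 1e-12:
            raise ValueError("stage_mix must sum to 1")


def generate_abundance_records(spec: SyntheticAbundanceSpec) -> pd.DataFrame:
    """Draw an abundance table whose filtered composition converges to
    the planted fractions.

    Non-decoy records are drawn inside the filter window (depth <= 100 m
    where the depth range allows it, fine mesh, adult/copepodite
    stages); decoys violate exactly one filter.  Abundance weights are
    lognormal, as plankton densities are.  The ``decoy`` column carries
    the planted label for oracle checks; the composition filters never
    look at it.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records

    orders = list(spec.true_fractions)
    probs = np.array([spec.true_fractions[o] for o in orders])
    order_col = rng.choice(orders, size=n, p=probs)

    lo, hi = spec.depth_range_m
    fine_mesh = [m for m in spec.mesh_values_um if 100.0 <= m <= 116.0]
    coarse_mesh = [m for m in spec.mesh_values_um if not 100.0 <= m <= 116.0]
    good_depth_hi = min(hi, 100.0)
    depth_feasible = lo <= good_depth_hi

    stages = [s for s in spec.stage_mix if s != "nauplius"]
    stage_p = np.array([spec.stage_mix[s] for s in stages])
    stage_p = stage_p / stage_p.sum() if stage_p.sum() > 0 else np.ones(len(stages)) / len(stages)

    decoy = rng.random(n) < DECOY_RATE
    depth = np.empty(n)
    mesh = np.empty(n)
    stage = np.empty(n, dtype=object)

    violations = rng.integers(0, 3, size=n)  # which filter a decoy breaks
    for i in range(n):
        is_decoy = decoy[i]
        v = violations[i]
        # depth
        if (is_decoy and v == 0) or not depth_feasible:
            depth[i] = rng.uniform(max(lo, 100.0 + 1e-9), max(hi, 101.0))
            decoy[i] = True
        else:
            depth[i] = rng.uniform(lo, good_depth_hi)
        # mesh
        if (is_decoy and v == 1 and coarse_mesh) or not fine_mesh:
            mesh[i] = rng.choice(coarse_mesh if coarse_mesh else list(spec.mesh_values_um))
            decoy[i] = True
        else:
            mesh[i] = rng.choice(fine_mesh)
        # stage
        if is_decoy and v == 2:
            stage[i] = "nauplius"
        else:
            stage[i] = rng.choice(stages, p=stage_p)

    return pd.DataFrame(
        {
            "station_id": [f"ST{rng.integers(1, 200):03d}" for _ in range(n)],
            "realm": spec.realm_label,
            "depth_m": depth,
            "mesh_um": mesh,
            "order": order_col,
            "stage": stage,
            "abundance": rng.lognormal(mean=2.0, sigma=1.0, size=n),
            "decoy": decoy,
        }
    )


# ---------------------------------------------------------------------------
# ingestion records


@dataclass(frozen=True)
class SyntheticIngestionSpec:
    """Recipe for ingestion-rate records following a log-log allometry.

    log10(ingestion) = log10(intercept) + exponent * log10(mass) + e,
    with e ~ Normal(0, noise_sd_log10) and masses log-uniform over
    ``mass_range_ugC``.
    """

    group: str = "calanoid"
    setting: str = "field"
    n: int = 100
    allometry_intercept: float = 0.05
    allometry_exponent: float = 1.0
    mass_range_ugC: tuple[float, float] = (1.0, 100.0)
    noise_sd_log10: float = 0.1
    diet: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"n={self.n} must be >= 3")
        if self.allometry_intercept <= 0:
            raise ValueError("allometry_intercept must be positive")
        if self.mass_range_ugC[0] <= 0 or self.mass_range_ugC[0] > self.mass_range_ugC[1]:
            raise ValueError(f"invalid mass_range_ugC {self.mass_range_ugC}")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be non-negative")


def generate_ingestion_records(spec: SyntheticIngestionSpec) -> pd.DataFrame:
    """Sample ingestion records from the planted allometry."""
    rng = np.random.default_rng(spec.seed)
    log_lo, log_hi = np.log10(spec.mass_range_ugC[0]), np.log10(spec.mass_range_ugC[1])
    mass = 10.0 ** rng.uniform(log_lo, log_hi, size=spec.n)
    log_ing = (
        np.log10(spec.allometry_intercept)
        + spec.allometry_exponent * np.log10(mass)
        + rng.normal(0.0, spec.noise_sd_log10, size=spec.n)
    )
    return pd.DataFrame(
        {
            "group": spec.group,
            "setting": spec.setting,
            "diet": spec.diet,
            "body_mass_ugC": mass,
            "ingestion_ugC_per_day": 10.0**log_ing,
        }
    )


def expected_wsir(spec: SyntheticIngestionSpec, mean_mass: float) -> float:
    """Noise-free WSIR implied by the planted allometry at a given mass."""
    return spec.allometry_intercept * mean_mass ** (spec.allometry_exponent - 1.0)


# ---------------------------------------------------------------------------
# clone libraries


@dataclass(frozen=True)
class SyntheticCloneSpec:
    """Recipe for a gut-content clone library with planted OTUs.

    OTU reference sequences are built from one random backbone by
    substituting disjoint site sets, guaranteeing every pair of
    references is at least ``between_otu_divergence`` apart.  Clone
    variation is confined to a shared pool of ``within * length`` sites
    disjoint from all distinguishing sites, so any two clones of the
    same OTU differ by at most ``within_otu_divergence``.  Substitutions
    only (no indels): divergence is Hamming distance over length.
    """

    n_copepods: int = 17
    n_otus: int = 4
    seq_length_bp: int = 200
    within_otu_divergence: float = 0.0
    between_otu_divergence: float = 0.10
    clones_per_copepod: int = 5
    incidence_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length_bp < 50:
            raise ValueError("seq_length_bp must be >= 50")
        if not 0 <= self.within_otu_divergence < self.between_otu_divergence <= 1:
            raise ValueError(
                "need 0 <= within_otu_divergence < between_otu_divergence <= 1"
            )
        if min(self.n_copepods, self.n_otus, self.clones_per_copepod) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.incidence_density <= 1.0:
            raise ValueError("incidence_density must be a proportion")
        sites_needed = (
            self.n_otus * math.ceil(self.between_otu_divergence * self.seq_length_bp / 2)
            + math.floor(self.within_otu_divergence * self.seq_length_bp)
        )
        if sites_needed > self.seq_length_bp:
            raise ValueError(
                f"divergence constraints need {sites_needed} sites but sequences "
                f"have only {self.seq_length_bp}"
            )


def _substitute(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace each listed site with a different base (guaranteed change)."""
    out = seq.copy()
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_clone_library(
    spec: SyntheticCloneSpec,
) -> tuple[list[CloneSequence], pd.DataFrame]:
    """Build a clone library and its planted copepod x OTU incidence.

    Returns the clones (FASTA-ready, headers ``copepodID|cloneN``) and
    the planted incidence matrix of clone counts.  Each copepod carries
    at least one OTU; extra OTUs are present with probability
    ``incidence_density``, and its clones are spread over its OTU set.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length_bp

    # Distinguishing sites: per-OTU disjoint blocks; any two references
    # then differ at >= between * L sites.
    per_otu = math.ceil(spec.between_otu_divergence * L / 2)
    shuffled = rng.permutation(L)
    backbone = rng.choice(_BASES, size=L)
    refs = []
    used = 0
    for k in range(spec.n_otus):
        sites = shuffled[used : used + per_otu]
        used += per_otu
        refs.append(_substitute(backbone, sites, rng))
    pool = shuffled[used : used + math.floor(spec.within_otu_divergence * L)]

    otu_ids = [f"OTU_{k + 1}" for k in range(spec.n_otus)]
    copepods = [f"cop{j + 1:02d}" for j in range(spec.n_copepods)]
    incidence = pd.DataFrame(0, index=copepods, columns=otu_ids, dtype=int)
    incidence.index.name = "copepod"

    clones: list[CloneSequence] = []
    for cop in copepods:
        present = np.flatnonzero(rng.random(spec.n_otus) < spec.incidence_density)
        if present.size == 0:
            present = np.array([rng.integers(spec.n_otus)])
        for c in range(spec.clones_per_copepod):
            k = int(rng.choice(present))
            seq = refs[k]
            if pool.size:
                n_mut = int(rng.integers(0, pool.size + 1))
                seq = _substitute(seq, rng.choice(pool, size=n_mut, replace=False), rng)
            clones.append(
                CloneSequence(
                    copepod_id=cop,
                    clone_id=f"clone{c + 1}",
                    sequence="".join(seq),
                )
            )
            incidence.loc[cop, otu_ids[k]] += 1

    return clones, incidence
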