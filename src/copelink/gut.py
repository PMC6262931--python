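"""Gut-content clone libraries: OTU clustering and diet incidence.

Metazoan prey DNA amplified from copepod digestive tracts (~200 bp 16S
fragments, five clones sequenced per copepod) is clustered into
operational taxonomic units (OTUs): sequences within 1% divergence are
treated as the same prey taxon, which absorbs intra-specific variation
and Taq polymerase error.  The copepod x OTU incidence matrix of clone
counts then yields diet summaries: distinct OTUs per oceanographic
condition (downwelling vs upwelling), per-copepod prey richness, and a
two-sample t test of richness between conditions.

The reference incidence matrix of prey detections in 17 copepod species
off the NW Iberian Peninsula ships with the package, so diet summaries
can be computed without sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from scipy import stats

CONDITIONS = ("downwelling", "upwelling")


@dataclass(frozen=True)
class CloneSequence:
    """One sequenced clone from a copepod gut-content library."""

    copepod_id: str
    clone_id: str
    sequence: str
    condition: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty clone sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    @property
    def key(self) -> str:
        return f"{self.copepod_id}|{self.clone_id}"


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_divergence(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Divergence between two sequences under global alignment.

    Sequences are aligned end-to-end (match 1, mismatch -1, gap -2 by
    default) and divergence is (mismatches + gap columns) / alignment
    length, a symmetric value in [0, 1].  On equal-length indel-free
    pairs this reduces to the Hamming distance over the length.
    """
    if not a or not b:
        raise ValueError("cannot compute divergence of an empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 0.0
    alignment = (aligner or _DEFAULT_ALIGNER).align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    diffs = sum(1 for x, y in zip(ga, gb) if x != y or x == "-" or y == "-")
    return diffs / len(ga)


@dataclass
class OtuClustering:
    """Result of clustering clone sequences at a divergence threshold."""

    threshold: float
    otu_assignments: dict[str, str]          # clone key -> OTU id
    representatives: dict[str, str]          # OTU id -> representative sequence
    incidence: pd.DataFrame                  # copepod x OTU clone counts
    taxonomy: pd.DataFrame | None = None     # optional OTU -> (phylum, label)

    @property
    def n_otus(self) -> int:
        return len(self.representatives)


def cluster_otus(
    clones: list[CloneSequence],
    threshold: float = 0.01,
    linkage: str = "centroid",
) -> OtuClustering:
    """Cluster clones into OTUs at a divergence threshold.

    The default greedy-centroid pass walks clones in input order: a
    clone joins the first OTU whose representative (founding sequence)
    is less than ``threshold`` divergent, otherwise it founds a new OTU.
    This guarantees every member is within the threshold of its
    representative and is deterministic for a fixed input order.

    ``linkage="single"`` instead joins a clone to any OTU containing a
    member within the threshold, merging OTUs that both qualify; this
    can chain clusters beyond the threshold diameter.
    """
    if not clones:
        raise ValueError("need at least one clone to cluster")
    if linkage not in ("centroid", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")

    assignments: dict[str, str] = {}
    reps: dict[str, str] = {}
    members: dict[str, list[CloneSequence]] = {}

    for clone in clones:
        if linkage == "centroid":
            target = None
            for otu_id, rep in reps.items():
                if pairwise_divergence(clone.sequence, rep) < threshold:
                    target = otu_id
                    break
        else:
            hits = [
                otu_id
                for otu_id, group in members.items()
                if any(pairwise_divergence(clone.sequence, m.sequence) < threshold for m in group)
            ]
            target = hits[0] if hits else None
            for merge_id in hits[1:]:          # chain: merge later hits into the first
                for m in members.pop(merge_id):
                    assignments[m.key] = target
                    members[target].append(m)
                reps.pop(merge_id)
        if target is None:
            target = f"OTU_{len(reps) + 1}"
            reps[target] = clone.sequence
            members[target] = []
        assignments[clone.key] = target
        members[target].append(clone)

    copepods = list(dict.fromkeys(c.copepod_id for c in clones))
    otu_ids = list(reps)
    counts = pd.DataFrame(0, index=copepods, columns=otu_ids, dtype=int)
    for clone in clones:
        counts.loc[clone.copepod_id, assignments[clone.key]] += 1
    counts.index.name = "copepod"

    return OtuClustering(
        threshold=threshold,
        otu_assignments=assignments,
        representatives=reps,
        incidence=counts,
    )


@dataclass(frozen=True)
class DietSummary:
    """Diet statistics derived from a copepod x OTU incidence matrix."""

    n_otus_total: int
    otus_per_condition: dict[str, int]
    richness_per_copepod: pd.Series
    richness_stats: pd.DataFrame             # per condition: n, mean, sd, min, max
    otus_per_phylum: dict[str, int] | None
    t_statistic: float
    p_value: float


def diet_summary(
    incidence: pd.DataFrame,
    condition_map: dict[str, str],
    taxonomy: pd.DataFrame | None = None,
    equal_var: bool = True,
) -> DietSummary:
    """Summarise diet incidence by oceanographic condition.

    ``incidence`` holds clone counts (copepod rows, OTU columns); a
    detection is any positive count.  ``condition_map`` assigns every
    copepod to a condition.  Richness between conditions is compared
    with a two-sided two-sample t test (Student, equal variances, by
    default; Welch with ``equal_var=False``).
    """
    if incidence.empty:
        raise ValueError("incidence matrix is empty")
    missing = [c for c in incidence.index if c not in condition_map]
    if missing:
        raise ValueError(f"copepod(s) without a condition label: {missing}")

    detected = incidence > 0
    conditions = pd.Series({c: condition_map[c] for c in incidence.index})
    richness = detected.sum(axis=1)
    richness.name = "richness"

    otus_per_condition = {
        cond: int(detected.loc[conditions == cond].any(axis=0).sum())
        for cond in conditions.unique()
    }
    rows = []
    groups: dict[str, np.ndarray] = {}
    for cond in conditions.unique():
        vals = richness[conditions == cond].to_numpy(dtype=float)
        groups[cond] = vals
        rows.append(
            {
                "condition": cond,
                "n_copepods": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "min": int(np.min(vals)),
                "max": int(np.max(vals)),
            }
        )
    stats_df = pd.DataFrame(rows).set_index("condition")

    if len(groups) == 2:
        g1, g2 = groups.values()
        if np.var(g1) == 0.0 and np.var(g2) == 0.0:
            # degenerate zero-variance case: identical means are a perfect
            # null (p = 1), distinct means a sure difference (p = 0)
            equal = np.mean(g1) == np.mean(g2)
            t_stat, p_val = (0.0, 1.0) if equal else (float("inf"), 0.0)
        else:
            t_stat, p_val = stats.ttest_ind(g1, g2, equal_var=equal_var)
    else:
        t_stat, p_val = float("nan"), float("nan")

    per_phylum = None
    if taxonomy is not None:
        detected_otus = detected.any(axis=0)
        tax = taxonomy.set_index("otu") if "otu" in taxonomy.columns else taxonomy
        per_phylum = (
            tax.loc[detected_otus[detected_otus].index, "phylum"].value_counts().to_dict()
        )

    return DietSummary(
        n_otus_total=int(detected.any(axis=0).sum()),
        otus_per_condition=otus_per_condition,
        richness_per_copepod=richness,
        richness_stats=stats_df,
        otus_per_phylum=per_phylum,
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )


def read_clone_fasta(path: str | Path, condition_map: dict[str, str] | None = None) -> list[CloneSequence]:
    """Read clones from a multi-FASTA with ``>copepodID|cloneN`` headers."""
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA header {rec.id!r} is not 'copepodID|cloneN'")
        cop, clone = rec.id.split("|", 1)
        clones.append(
            CloneSequence(
                copepod_id=cop,
                clone_id=clone,
                sequence=str(rec.seq),
                condition=(condition_map or {}).get(cop),
            )
        )
    return clones


def write_clone_fasta(clones: list[CloneSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clones:
            fh.write(f">{c.key}\n{c.sequence}\n")


def load_reference_incidence() -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Load the packaged reference diet-incidence matrix.

    Returns ``(incidence, condition_map, taxonomy)``: clone counts of 16
    prey OTUs across 17 copepod species sampled under downwelling (C1 to
    C7) and upwelling (C8 to C17) conditions, plus the phylum/taxon
    labels of each OTU.
    """
    pkg = resources.files("copelink") / "data"
    raw = pd.read_csv(pkg / "diet_incidence.csv")
    taxonomy = pd.read_csv(pkg / "diet_otu_taxonomy.csv")
    condition_map = dict(zip(raw["copepod"], raw["condition"]))
    incidence = raw.drop(columns=["condition", "species", "size_class"]).set_index("copepod")
    incidence.columns.name = "otu"
    return incidence, condition_map, taxonomy
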