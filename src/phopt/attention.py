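"""Interpretation of residue attention weights.

The per-position mean of the head weight vectors, ``w_avg``, inherits the
simplex property (non-negative, sums to 1 over the L residues) and is the
interpretability signal mapped onto the sequence. Because raw ``w_avg``
entries from sequences of different lengths are not comparable (a uniform
head puts 1/L on every residue), cross-sequence statistics always use
*length-normalized* weights ``L * w_avg``, whose null expectation is 1 per
residue regardless of length. Min-max "normalized" weights are used only for
display profiles.

Residue chemical classes (a standard textbook partition of the 20 letters):
acidic D/E; basic K/R/H; polar uncharged S/T/N/Q/C/Y; nonpolar
G/A/V/L/I/P/F/M/W. Ambiguity codes are unlabeled and excluded from class
statistics. Enzyme strata mirror the evaluation ranges: acidophilic
pH_opt < 6, alkaliphilic pH_opt > 8, neutrophilic otherwise.

All comparisons use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError
from .io import AnnotationTrack, ProteinRecord
from .network import AttentionResult

ACIDIC = "acidic"
BASIC = "basic"
POLAR = "polar_uncharged"
NONPOLAR = "nonpolar"

RESIDUE_CLASSES: dict[str, str] = {}
for aa in "DE":
    RESIDUE_CLASSES[aa] = ACIDIC
for aa in "KRH":
    RESIDUE_CLASSES[aa] = BASIC
for aa in "STNQCY":
    RESIDUE_CLASSES[aa] = POLAR
for aa in "GAVLIPFMW":
    RESIDUE_CLASSES[aa] = NONPOLAR

IONIZABLE = set("DEKRH")

STRATA = ("acidophilic", "neutrophilic", "alkaliphilic")


def stratify_by_ph(ph_opt: float) -> str:
    """acidophilic < 6 <= neutrophilic <= 8 < alkaliphilic."""
    if ph_opt < 6.0:
        return "acidophilic"
    if ph_opt > 8.0:
        return "alkaliphilic"
    return "neutrophilic"


def average_attention(attention: AttentionResult) -> np.ndarray:
    """Head-averaged weights ``w_avg``: mean over heads, one value per residue.

    Preserves the simplex property: entries are non-negative and sum to 1
    over the unmasked positions.
    """
    w = np.asarray(attention.weights)
    if w.ndim != 2:
        raise ContractError("average_attention expects a single-sequence "
                            "AttentionResult (n_head x L weights)")
    return w.mean(axis=0)


def classify_residues(sequence: str) -> list[str | None]:
    """Chemical class label per residue; ambiguity codes map to ``None``."""
    return [RESIDUE_CLASSES.get(aa) for aa in sequence.upper()]


@dataclass
class ResidueWeightProfile:
    """Per-residue attention weights for one sequence, with annotations."""

    id: str
    sequence: str
    weights: np.ndarray                 # w_avg, sums to 1 over L
    active_sites: set[int] = field(default_factory=set)   # 1-based
    binding_sites: set[int] = field(default_factory=set)  # 1-based

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.sequence),):
            raise ContractError(
                f"{self.id}: {len(self.weights)} weights for a "
                f"{len(self.sequence)}-residue sequence")
        if (self.weights < -1e-12).any():
            raise ContractError(f"{self.id}: negative attention weight")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def normalized_weights(self) -> np.ndarray:
        """Min-max rescaled weights in [0, 1] (display only)."""
        lo, hi = self.weights.min(), self.weights.max()
        if hi == lo:
            return np.zeros_like(self.weights)
        return (self.weights - lo) / (hi - lo)

    @property
    def length_normalized_weights(self) -> np.ndarray:
        """``L * w_avg``; null expectation 1 per residue, any length."""
        return self.length * self.weights

    @property
    def residue_classes(self) -> list[str | None]:
        return classify_residues(self.sequence)

    def site_mask(self) -> np.ndarray:
        """Boolean per position: annotated as active or binding site."""
        m = np.zeros(self.length, dtype=bool)
        for pos in self.active_sites | self.binding_sites:
            m[pos - 1] = True
        return m


def build_profile(record: ProteinRecord, attention: AttentionResult,
                  annotations: Mapping[str, AnnotationTrack] | None = None,
                  ) -> ResidueWeightProfile:
    """Assemble a profile from a model's attention output and annotations."""
    w = average_attention(attention)
    track = (annotations or {}).get(record.id)
    if track is not None:
        track.validate_against(record.sequence)
    return ResidueWeightProfile(
        id=record.id, sequence=record.sequence, weights=w,
        active_sites=set(track.active_sites) if track else set(),
        binding_sites=set(track.binding_sites) if track else set(),
    )


# ---------------------------------------------------------------------------
# class-weight comparison
# ---------------------------------------------------------------------------

@dataclass
class ClassWeightSummary:
    """Length-normalized weights pooled by (stratum, residue class).

    ``pooled[(stratum, cls)]`` is the vector of per-residue weights;
    ``pairwise`` holds two-sided Mann-Whitney results, keyed either by
    (cls, stratum_a, stratum_b) for cross-strata comparisons within a class
    or by (stratum, cls_a, cls_b) for class comparisons within a stratum.
    """

    pooled: dict[tuple[str, str], np.ndarray]
    pairwise: dict[tuple, tuple[float, float]]
    notices: list[str] = field(default_factory=list)

    def compare(self, stratum_a: str, class_a: str,
                stratum_b: str, class_b: str) -> tuple[float, float]:
        a = self.pooled.get((stratum_a, class_a))
        b = self.pooled.get((stratum_b, class_b))
        if a is None or b is None or len(a) == 0 or len(b) == 0:
            raise ContractError("empty group in comparison")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)


def class_weight_comparison(profiles: Sequence[ResidueWeightProfile],
                            strata: Mapping[str, str]) -> ClassWeightSummary:
    """Pool length-normalized per-residue weights by stratum and class.

    ``strata`` maps profile id -> stratum name (use :func:`stratify_by_ph`
    on experimental labels). Pairwise rank tests are run between strata for
    each residue class and between classes within each stratum; comparisons
    involving an empty group are skipped with a notice.
    """
    classes = (ACIDIC, BASIC, POLAR, NONPOLAR)
    pooled: dict[tuple[str, str], list[float]] = {
        (s, c): [] for s in STRATA for c in classes}
    for prof in profiles:
        stratum = strata.get(prof.id)
        if stratum is None:
            raise ContractError(f"no stratum assigned for profile {prof.id!r}")
        lw = prof.length_normalized_weights
        for w, cls in zip(lw, prof.residue_classes):
            if cls is not None:
                pooled[(stratum, cls)].append(float(w))
    pooled_arr = {k: np.asarray(v) for k, v in pooled.items()}

    pairwise: dict[tuple, tuple[float, float]] = {}
    notices: list[str] = []

    def test(key, a, b):
        if len(a) == 0 or len(b) == 0:
            notices.append(f"comparison {key} skipped: empty group")
            return
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        pairwise[key] = (float(res.statistic), float(res.pvalue))

    for cls in classes:
        for sa, sb in combinations(STRATA, 2):
            test((cls, sa, sb), pooled_arr[(sa, cls)], pooled_arr[(sb, cls)])
    for stratum in STRATA:
        for ca, cb in combinations(classes, 2):
            test((stratum, ca, cb),
                 pooled_arr[(stratum, ca)], pooled_arr[(stratum, cb)])
    return ClassWeightSummary(pooled_arr, pairwise, notices)


# ---------------------------------------------------------------------------
# site enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float
    p_value: float
    median_site_weight: float
    median_other_weight: float
    median_ratio: float
    n_site: int
    n_other: int


def site_enrichment(profiles: Sequence[ResidueWeightProfile],
                    annotations: Mapping[str, AnnotationTrack] | None = None,
                    ) -> EnrichmentResult:
    """Are attention weights higher at annotated active/binding sites?

    Pools length-normalized weights at annotated positions against all other
    positions across sequences and runs a two-sided Mann-Whitney U test; the
    effect size is the ratio of median site weight to median non-site weight.
    """
    site_w: list[float] = []
    other_w: list[float] = []
    for prof in profiles:
        if annotations is not None:
            track = annotations.get(prof.id)
            sites = set()
            if track is not None:
                track.validate_against(prof.sequence)
                sites = track.active_sites | track.binding_sites
        else:
            sites = prof.active_sites | prof.binding_sites
        lw = prof.length_normalized_weights
        for pos0, w in enumerate(lw):
            (site_w if pos0 + 1 in sites else other_w).append(float(w))
    if not site_w:
        raise ContractError("no annotated sites in any profile")
    res = stats.mannwhitneyu(site_w, other_w, alternative="two-sided")
    med_s = float(np.median(site_w))
    med_o = float(np.median(other_w))
    return EnrichmentResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        median_site_weight=med_s, median_other_weight=med_o,
        median_ratio=med_s / med_o if med_o > 0 else np.inf,
        n_site=len(site_w), n_other=len(other_w),
    )


# ---------------------------------------------------------------------------
# per-sequence profile report
# ---------------------------------------------------------------------------

@dataclass
class ProfileReport:
    profile: ResidueWeightProfile
    table: pd.DataFrame
    peaks: list[int]  # 1-based positions of top local maxima

    def plot(self, ax=None):
        """Weight profile: blue dashed curve = normalized weights, orange
        dots = binding sites, red dots = active sites."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        pos = np.arange(1, self.profile.length + 1)
        nw = self.profile.normalized_weights
        ax.plot(pos, nw, "b--", lw=1, label="normalized attention")
        for p in sorted(self.profile.binding_sites):
            ax.plot(p, nw[p - 1], "o", color="orange", label="binding site"
                    if p == min(self.profile.binding_sites) else None)
        for p in sorted(self.profile.active_sites):
            ax.plot(p, nw[p - 1], "o", color="red", label="active site"
                    if p == min(self.profile.active_sites) else None)
        ax.set_xlabel("residue position")
        ax.set_ylabel("normalized weight")
        ax.set_title(self.profile.id)
        ax.legend(loc="upper right", fontsize=7)
        return ax


def _local_maxima(w: np.ndarray) -> np.ndarray:
    """0-based indices of local maxima (plateau edges and ends count)."""
    L = len(w)
    if L == 1:
        return np.array([0])
    left = np.r_[-np.inf, w[:-1]]
    right = np.r_[w[1:], -np.inf]
    return np.flatnonzero((w >= left) & (w > right) |
                          ((w > left) & (w >= right)))


def profile_report(profile: ResidueWeightProfile,
                   peak_quantile: float = 0.90) -> ProfileReport:
    """Per-position table plus attention peaks.

    Peaks are local maxima of ``w_avg`` whose weight is at or above the given
    quantile of the profile's weights.
    """
    w = profile.weights
    table = pd.DataFrame({
        "position": np.arange(1, profile.length + 1),
        "residue": list(profile.sequence),
        "weight": w,
        "normalized_weight": profile.normalized_weights,
        "residue_class": profile.residue_classes,
        "is_active_site": [i + 1 in profile.active_sites
                           for i in range(profile.length)],
        "is_binding_site": [i + 1 in profile.binding_sites
                            for i in range(profile.length)],
    })
    thresh = np.quantile(w, peak_quantile)
    peaks = [int(i) + 1 for i in _local_maxima(w) if w[i] >= thresh]
    return ProfileReport(profile=profile, table=table, peaks=peaks)


# ---------------------------------------------------------------------------
# sidecar I/O
# ---------------------------------------------------------------------------

def write_weight_sidecar(profiles: Sequence[ResidueWeightProfile],
                         path: str | Path) -> None:
    """TSV with one row per (sequence, position)."""
    frames = [profile_report(p).table.assign(id=p.id) for p in profiles]
    df = pd.concat(frames, ignore_index=True)
    cols = ["id", "position", "residue", "weight", "normalized_weight",
            "residue_class", "is_active_site", "is_binding_site"]
    df[cols].to_csv(path, sep="\t", index=False)


def read_weight_sidecar(path: str | Path) -> list[ResidueWeightProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for id_, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        profiles.append(ResidueWeightProfile(
            id=str(id_),
            sequence="".join(grp["residue"]),
            weights=grp["weight"].to_numpy(),
            active_sites=set(grp.loc[grp["is_active_site"],
                                     "position"].astype(int)),
            binding_sites=set(grp.loc[grp["is_binding_site"],
                                      "position"].astype(int)),
        ))
    return profiles
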