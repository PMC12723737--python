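"""Predictor-guided single-point mutation screening.

The screen enumerates every non-wild-type substitution at every position
within +/- ``radius`` of each center site (overlapping windows deduplicated,
windows clipped at the sequence ends), predicts each mutant's optimal pH, and
flags candidates whose predicted pH_opt falls below a threshold. An optional
external activity scorer (e.g. a turnover-number predictor) can additionally
rank threshold-passing candidates — ascending predicted pH_opt, ties broken
by descending activity — keeping the best ``top_k``.

The reference use case screens 3 windows of 21 sites each (centers at three
substrate-binding residues, -10 to +10): 63 positions x 19 substitutions =
1197 mutant sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embed import Embedder
from .exceptions import ParseError, ValidationError
from .io import STANDARD_AA
from .network import ModelState, predict_batch

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single-point substitution, named UniProt-style (e.g. ``H44C``)."""

    position: int  # 1-based
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position {self.position} is not 1-based")
        if self.mut_aa == self.wt_aa:
            raise ValidationError(f"{self.name}: mutant equals wild type")
        if self.mut_aa not in STANDARD_AA:
            raise ValidationError(f"{self.name}: {self.mut_aa!r} is not a "
                                  "standard amino acid")

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def validate_against(self, sequence: str) -> None:
        if self.position > len(sequence):
            raise ValidationError(
                f"{self.name}: position exceeds sequence length "
                f"{len(sequence)}")
        found = sequence[self.position - 1]
        if found != self.wt_aa:
            raise ValidationError(
                f"{self.name}: expected wild-type {self.wt_aa!r} at position "
                f"{self.position}, found {found!r}")


def parse_mutation(name: str) -> MutationSpec:
    m = _MUTATION_RE.match(name.strip())
    if not m:
        raise ParseError(f"malformed mutation name {name!r} "
                         "(expected e.g. 'H44C')")
    return MutationSpec(position=int(m.group(2)), wt_aa=m.group(1),
                        mut_aa=m.group(3))


@dataclass(frozen=True)
class ScreenConfig:
    """Windowed saturation-mutagenesis screen parameters."""

    centers: tuple[int, ...]
    radius: int = 10
    ph_threshold: float = 7.0
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValidationError("radius must be >= 0")
        if not self.centers:
            raise ValidationError("at least one center site required")
        object.__setattr__(self, "centers", tuple(self.centers))


def window_positions(sequence: str, config: ScreenConfig) -> list[int]:
    """Union of clipped windows [center - radius, center + radius], sorted."""
    L = len(sequence)
    positions: set[int] = set()
    for c in config.centers:
        if not 1 <= c <= L:
            raise ValidationError(
                f"center {c} outside sequence of length {L}")
        positions.update(range(max(1, c - config.radius),
                               min(L, c + config.radius) + 1))
    return sorted(positions)


def enumerate_mutants(sequence: str, config: ScreenConfig) -> list[MutationSpec]:
    """All 19 non-wild-type substitutions at every window position.

    Canonical order: position ascending, then mutant letter alphabetical.
    Positions holding a non-standard residue raise a validation error naming
    the position.
    """
    sequence = sequence.upper()
    specs: list[MutationSpec] = []
    for pos in window_positions(sequence, config):
        wt = sequence[pos - 1]
        if wt not in STANDARD_AA:
            raise ValidationError(
                f"non-standard residue {wt!r} at position {pos} inside a "
                "mutagenesis window")
        for aa in STANDARD_AA:
            if aa != wt:
                specs.append(MutationSpec(position=pos, wt_aa=wt, mut_aa=aa))
    return specs


def apply_mutation(sequence: str, spec: MutationSpec) -> str:
    """Single-character substitution; length and all other positions kept."""
    spec.validate_against(sequence)
    i = spec.position - 1
    return sequence[:i] + spec.mut_aa + sequence[i + 1:]


ActivityScorer = Callable[[str], float]


@dataclass
class CandidateTable:
    """Screen output: one row per enumerated mutant.

    ``frame`` columns: mutation, position, wt, mut, predicted_ph_opt,
    activity_score, selected, error. ``selected`` implies
    predicted_ph_opt < ph_threshold.
    """

    frame: pd.DataFrame
    config: ScreenConfig | None = None
    errors: int = 0

    @property
    def selected(self) -> pd.DataFrame:
        return self.frame[self.frame["selected"]]

    def __len__(self) -> int:
        return len(self.frame)


def screen(sequence: str, config: ScreenConfig, model_state: ModelState,
           embedder: Embedder,
           activity_scorer: ActivityScorer | Mapping[str, float] | None = None,
           batch_size: int = 64) -> CandidateTable:
    """Score every enumerated mutant and select candidates below the threshold.

    Deterministic for fixed inputs. A scorer failure on one mutant flags that
    row as errored and the screen continues; the table reports the error
    count.
    """
    sequence = sequence.upper()
    specs = enumerate_mutants(sequence, config)
    mutated = [apply_mutation(sequence, s) for s in specs]
    preds = predict_batch(model_state, mutated, embedder,
                          batch_size=batch_size)

    scores: list[float] = []
    errors: list[bool] = []
    for spec, seq in zip(specs, mutated):
        if activity_scorer is None:
            scores.append(np.nan)
            errors.append(False)
            continue
        try:
            if callable(activity_scorer):
                scores.append(float(activity_scorer(seq)))
            else:
                scores.append(float(activity_scorer[spec.name]))
            errors.append(False)
        except Exception:
            scores.append(np.nan)
            errors.append(True)

    frame = pd.DataFrame({
        "mutation": [s.name for s in specs],
        "position": [s.position for s in specs],
        "wt": [s.wt_aa for s in specs],
        "mut": [s.mut_aa for s in specs],
        "predicted_ph_opt": preds,
        "activity_score": scores,
        "selected": False,
        "error": errors,
    })
    passing = (frame["predicted_ph_opt"] < config.ph_threshold) & ~frame["error"]
    if activity_scorer is not None and config.top_k is not None:
        # rank threshold-passers: lowest predicted pH first, then highest
        # activity; keep top_k
        ranked = frame[passing].sort_values(
            ["predicted_ph_opt", "activity_score"],
            ascending=[True, False], kind="mergesort")
        frame.loc[ranked.index[:config.top_k], "selected"] = True
    else:
        frame.loc[passing, "selected"] = True
    return CandidateTable(frame=frame, config=config, errors=int(sum(errors)))


def write_candidates(table: CandidateTable, path: str | Path) -> None:
    """Write the candidate table as TSV, rows in canonical order."""
    df = table.frame.sort_values(["position", "mut"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> CandidateTable:
    df = pd.read_csv(path, sep="\t")
    for name in df["mutation"]:
        parse_mutation(str(name))  # raises ParseError on malformed names
    df["activity_score"] = df["activity_score"].astype(float)
    return CandidateTable(frame=df.reset_index(drop=True),
                          errors=int(df["error"].sum()) if "error" in df else 0)
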