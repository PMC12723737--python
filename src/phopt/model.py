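"""High-level modelling interface.

:class:`OptimalPHRegressor` is built from labeled records (or a DataFrame /
dataset file); ``fit()`` runs the training protocol and returns an
:class:`OptimalPHResults` carrying the trained state, the per-epoch history,
dev-set diagnostics and a ``summary()`` table. Prediction, stratified
evaluation, attention interpretation and the mutational screen all hang off
the results object.

Example
-------
>>> from phopt import synth, model
>>> from phopt.embed import FixtureEmbedder
>>> recs = synth.generate_dataset(synth.SyntheticSpec(n=300, seed=7))
>>> reg = model.OptimalPHRegressor(recs, embedder=FixtureEmbedder(dim=16, seed=7),
...                                dim=16, seed=7)
>>> res = reg.fit(n_epochs=5)
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .attention import ResidueWeightProfile, build_profile
from .embed import Embedder, FixtureEmbedder, embed_sequence
from .exceptions import ContractError
from .io import AnnotationTrack, LabeledRecord, ProteinRecord
from .metrics import EvalReport, stratified_report
from .mutate import CandidateTable, ScreenConfig, screen
from .network import (ModelConfig, ModelState, forward, load_checkpoint,
                      predict_batch, predict_ph, save_checkpoint)
from .train import TrainingConfig, train


class OptimalPHRegressor:
    """Sequence-based regressor of enzyme optimal pH.

    Parameters
    ----------
    records : labeled (sequence, pH_opt) records
    embedder : per-residue embedding backend; defaults to the deterministic
        fixture embedder at the configured dimension
    config : full :class:`ModelConfig`, or pass individual fields as keyword
        arguments (``dim``, ``n_head``, ``n_rd``, ``window_sizes``, ``seed``).
    """

    def __init__(self, records: Sequence[LabeledRecord],
                 embedder: Embedder | None = None,
                 config: ModelConfig | None = None, **config_kwargs):
        if not records:
            raise ContractError("no training records supplied")
        self.records = list(records)
        if config is None:
            config = ModelConfig(**config_kwargs)
        elif config_kwargs:
            raise ContractError("pass either config or keyword fields, not both")
        self.config = config
        self.embedder = embedder if embedder is not None else FixtureEmbedder(
            dim=config.dim, seed=config.seed)
        if self.embedder.dim != config.dim:
            raise ContractError(
                f"embedder dim {self.embedder.dim} != model dim {config.dim}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "OptimalPHRegressor":
        """Build from a DataFrame with id/sequence/ph_opt (+ ec, identity)."""
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            ec = d.get("ec")
            ident = d.get("identity")
            records.append(LabeledRecord(
                id=str(d["id"]), sequence=str(d["sequence"]),
                ph_opt=float(d["ph_opt"]),
                ec_class=int(ec) if ec is not None and pd.notna(ec) else None,
                identity_score=(float(ident) if ident is not None
                                and pd.notna(ident) else None)))
        return cls(records, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, colmap=None,
                  **kwargs) -> "OptimalPHRegressor":
        """Build from a TSV/CSV dataset table."""
        return cls(_io.read_dataset(path, colmap=colmap), **kwargs)

    def fit(self, training_config: TrainingConfig | None = None,
            **training_kwargs) -> "OptimalPHResults":
        """Run the training protocol and return fitted results."""
        if training_config is None:
            training_config = TrainingConfig(**training_kwargs)
        elif training_kwargs:
            raise ContractError(
                "pass either training_config or keyword fields, not both")
        state, history = train(self.config, training_config, self.records,
                               self.embedder)
        return OptimalPHResults(self, state, history, training_config)


class OptimalPHResults:
    """Fitted model: trained state, history, diagnostics, downstream analyses."""

    def __init__(self, model: OptimalPHRegressor | None, state: ModelState,
                 history: pd.DataFrame | None = None,
                 training_config: TrainingConfig | None = None,
                 embedder: Embedder | None = None):
        self.model = model
        self.state = state
        self.history = history
        self.training_config = training_config
        self.embedder = embedder if embedder is not None else (
            model.embedder if model is not None else
            FixtureEmbedder(dim=state.config.dim, seed=state.config.seed))

    # -- prediction --------------------------------------------------------

    def predict(self, sequences, clamp: bool = True) -> np.ndarray:
        """Predicted optimal pH for sequences / records (pH units)."""
        if isinstance(sequences, (str, ProteinRecord)):
            return np.array([predict_ph(self.state, sequences, self.embedder,
                                        clamp=clamp)])
        seqs = [s.sequence if hasattr(s, "sequence") else s for s in sequences]
        return predict_batch(self.state, seqs, self.embedder, clamp=clamp)

    # -- diagnostics -------------------------------------------------------

    @property
    def best_epoch(self) -> int | None:
        if self.history is None:
            return None
        return int(self.history["dev_rmse"].idxmin())

    def evaluate(self, records: Sequence[LabeledRecord],
                 include_ec7: bool = False) -> EvalReport:
        """Stratified evaluation of this model on labeled records."""
        preds = self.predict([r.sequence for r in records])
        return stratified_report(records, preds, include_ec7=include_ec7)

    def summary(self) -> str:
        """Text summary: architecture, training setup and dev diagnostics."""
        c = self.state.config
        lines = [
            "Optimal-pH regression results",
            "=" * 46,
            f"{'embedding dim':<28}{c.dim}",
            f"{'attention heads':<28}{c.n_head}",
            f"{'residual dense blocks':<28}{c.n_rd}",
            f"{'CNN window sizes':<28}{','.join(map(str, c.window_sizes))}",
            f"{'parameters':<28}{sum(v.size for v in self.state.params.values())}",
        ]
        if self.training_config is not None:
            t = self.training_config
            lines += [
                f"{'batch size':<28}{t.batch_size}",
                f"{'initial lr':<28}{t.initial_lr}",
                f"{'lr decay':<28}x{t.lr_decay_factor} every "
                f"{t.lr_decay_every} epochs",
                f"{'epochs':<28}{t.n_epochs}",
            ]
        if self.history is not None and len(self.history):
            best = self.history.loc[self.best_epoch]
            lines += [
                "-" * 46,
                f"{'best epoch (dev RMSE)':<28}{int(best['epoch'])}",
                f"{'dev RMSE (pH units)':<28}{best['dev_rmse']:.4f}",
                f"{'dev MAE (pH units)':<28}{best['dev_mae']:.4f}",
                f"{'dev R^2':<28}{best['dev_r2']:.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- interpretation ----------------------------------------------------

    def attention_profile(self, record: ProteinRecord | str,
                          annotations: Mapping[str, AnnotationTrack] | None = None,
                          ) -> ResidueWeightProfile:
        """Head-averaged residue attention weights for one sequence."""
        if isinstance(record, str):
            record = ProteinRecord("query", record)
        r = embed_sequence(self.embedder, record)
        _, attn = forward(self.state, r)
        return build_profile(record, attn, annotations)

    # -- screening ---------------------------------------------------------

    def screen(self, sequence: ProteinRecord | str, config: ScreenConfig,
               activity_scorer=None) -> CandidateTable:
        """Predictor-guided single-point mutation screen on this model."""
        seq = sequence.sequence if hasattr(sequence, "sequence") else sequence
        return screen(seq, config, self.state, self.embedder,
                      activity_scorer=activity_scorer)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.state, path)

    @classmethod
    def load(cls, path: str | Path,
             embedder: Embedder | None = None) -> "OptimalPHResults":
        state = load_checkpoint(path)
        return cls(model=None, state=state, embedder=embedder)
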