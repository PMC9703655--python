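"""Model / Results interface over the two-stage fusion network.

:class:`DrugResponseModel` is built from a :class:`MultiOmicsDataset` (or
from plain DataFrames via :meth:`DrugResponseModel.from_dataframes`);
``fit`` runs both training stages and returns a
:class:`DrugResponseResults` carrying the fitted parameters, the attention
scores, training diagnostics and a ``summary()`` table. Cross-validation
and ablation hang off the model; prediction, attention reporting and
checkpointing hang off the results.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ofio
from .datatypes import DrugResponseTable, MultiOmicsDataset, OmicsMatrix, InteractomeEdges
from .layers import attention_scores, fuse_and_predict, subnetwork_forward
from .metrics import (
    PredictionSet,
    attention_report,
    evaluate_predictions,
    mse,
    r_squared,
    top_k_accuracy,
)
from .preprocess import align_cell_lines, build_adjacency, standardize
from .training import (
    CrossValidationResult,
    TrainingConfig,
    ablation_run,
    cross_validate,
    train_attention,
    train_subnetwork,
)

__version__ = "0.1.0"


class DrugResponseModel:
    """Interactome-masked multi-omics network for log-IC50 regression."""

    def __init__(self, dataset: MultiOmicsDataset,
                 config: Optional[TrainingConfig] = None):
        self.dataset = dataset
        self.config = config or TrainingConfig()

    @classmethod
    def from_dataframes(cls, blocks: dict, responses: pd.DataFrame,
                        edges: Optional[InteractomeEdges] = None,
                        embedding_kinds: Optional[dict] = None,
                        config: Optional[TrainingConfig] = None,
                        missing_token: str = "NA") -> "DrugResponseModel":
        """Build from pandas objects.

        ``blocks`` maps omics name -> (cell lines x features) DataFrame;
        ``responses`` is a (cell lines x drugs) DataFrame whose NaN entries
        are treated as unobserved. Graph-embedded blocks (per
        ``embedding_kinds``, default dense) get an adjacency built from
        ``edges``. Cell lines are aligned by sorted intersection.
        """
        embedding_kinds = embedding_kinds or {}
        omics = []
        for name, df in blocks.items():
            kind = embedding_kinds.get(name, "dense")
            omics.append(OmicsMatrix(name, list(df.index), list(df.columns),
                                     df.to_numpy(dtype=float), kind))
        vals = responses.to_numpy(dtype=float)
        mask = np.isfinite(vals)
        vals = np.where(mask, vals, 0.0)
        resp = DrugResponseTable(list(responses.index), list(responses.columns),
                                 vals, mask)
        adjacency = {}
        for m in omics:
            if m.embedding_kind == "graph":
                if edges is None:
                    raise ValueError(
                        f"block {m.omics_name!r} uses graph embedding but no "
                        "interactome edges were given"
                    )
                adjacency[m.omics_name] = build_adjacency(edges, m.feature_ids)
        data = align_cell_lines(omics, resp, adjacency)
        return cls(data, config)

    def fit(self, seed: Optional[int] = None,
            record_history: bool = False) -> "DrugResponseResults":
        """Run both training stages on all cell lines.

        Stage 1 fits one sub-network per omics block (inputs standardized on
        the full data); stage 2 freezes them and learns the attention fusion.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        from .training import _fold_seeds
        seeds = _fold_seeds(seed, self.dataset.n_blocks + 1)
        subnets, stats, Xs, history = {}, {}, [], {}
        resp = self.dataset.responses
        for block, s in zip(self.dataset.omics_blocks, seeds):
            std_block, st = standardize(block)
            adj = self.dataset.adjacency.get(block.omics_name)
            p, h = train_subnetwork(std_block, resp, adj, cfg, seed=s,
                                    record_history=record_history)
            subnets[block.omics_name] = p
            stats[block.omics_name] = st
            Xs.append(std_block.values)
            history[f"stage1/{block.omics_name}"] = h
        att, h = train_attention(
            list(subnets.values()), Xs, resp.values, resp.observed_mask,
            cfg, seed=seeds[-1], record_history=record_history,
        )
        history["stage2/attention"] = h
        return DrugResponseResults(self, subnets, att, stats, seed, history)

    def cross_validate(self, seed: Optional[int] = None) -> CrossValidationResult:
        return cross_validate(self.dataset, self.config, seed=seed)

    def ablate(self, seed: Optional[int] = None, subsets=None,
               retrain_subnetworks: bool = False) -> pd.DataFrame:
        return ablation_run(self.dataset, self.config, subsets=subsets,
                            seed=seed, retrain_subnetworks=retrain_subnetworks)


class DrugResponseResults:
    """Fitted parameters, diagnostics and reports of a two-stage fit."""

    def __init__(self, model: DrugResponseModel, subnetworks: dict,
                 attention, stats: dict, seed: int, history: dict):
        self.model = model
        self.subnetworks = subnetworks
        self.attention = attention
        self.stats = stats
        self.seed = seed
        self.history = history
        self._omics_names = model.dataset.block_names()
        self._drug_ids = model.dataset.responses.drug_ids

    # -- predictions ------------------------------------------------------

    def _standardized_inputs(self, blocks: list) -> list:
        Xs = []
        for block in blocks:
            std, _ = standardize(block, self.stats[block.omics_name])
            Xs.append(std.values)
        return Xs

    def predict(self, dataset: Optional[MultiOmicsDataset] = None) -> pd.DataFrame:
        """Predicted log IC50 for every cell line x drug."""
        data = dataset or self.model.dataset
        blocks = [data.block(n) for n in self._omics_names]
        Xs = self._standardized_inputs(blocks)
        heads = [subnetwork_forward(X, self.subnetworks[n])
                 for X, n in zip(Xs, self._omics_names)]
        pred = fuse_and_predict(heads, self.attention)
        return pd.DataFrame(pred, index=data.cell_line_ids, columns=self._drug_ids)

    @property
    def fittedvalues(self) -> pd.DataFrame:
        return self.predict()

    def prediction_set(self, dataset: Optional[MultiOmicsDataset] = None) -> PredictionSet:
        data = dataset or self.model.dataset
        pred = self.predict(data)
        return PredictionSet(pred.to_numpy(), data.responses.values,
                             data.responses.observed_mask,
                             data.responses.drug_ids, data.cell_line_ids)

    def evaluate(self, dataset: Optional[MultiOmicsDataset] = None):
        return evaluate_predictions(self.prediction_set(dataset),
                                    self.attention_scores_)

    # -- attention --------------------------------------------------------

    @property
    def attention_scores_(self) -> pd.DataFrame:
        """Per-omics attention score of every drug (columns sum to 1)."""
        return pd.DataFrame(attention_scores(self.attention.normalized()),
                            index=self._omics_names, columns=self._drug_ids)

    def plot_attention(self, out_png=None, out_tsv=None) -> pd.DataFrame:
        return attention_report(self.attention_scores_.to_numpy(),
                                self._omics_names, self._drug_ids,
                                out_tsv=out_tsv, out_png=out_png)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        data = self.model.dataset
        cfg = self.model.config
        ps = self.prediction_set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = (mse(ps), r_squared(ps),
                     top_k_accuracy(ps, 1), top_k_accuracy(ps, 3))
        mean_att = self.attention_scores_.mean(axis=1)
        w = 72
        lines = [
            "Multi-omics drug response fusion model".center(w),
            "=" * w,
            f"No. cell lines: {data.responses.n_cells:<8} No. drugs: "
            f"{data.responses.n_drugs:<8} Omics blocks: {data.n_blocks}",
            f"Optimizer: Adam (lr={cfg.learning_rate})   Seed: {self.seed}",
            f"Epochs: graph {cfg.epochs_graph} / dense {cfg.epochs_dense} / "
            f"attention {cfg.epochs_attention}",
            "-" * w,
            f"Training MSE: {stats[0]:.4f}   R2: {stats[1]:.4f}   "
            f"Top-1: {stats[2]:.1f}%   Top-3: {stats[3]:.1f}%",
            "-" * w,
            f"{'omics':<14}{'embedding':<11}{'n_feat':>7}{'hidden':>8}"
            f"{'dropout':>9}{'mean attention':>18}",
        ]
        for b in data.omics_blocks:
            lines.append(
                f"{b.omics_name:<14}{b.embedding_kind:<11}{b.n_features:>7}"
                f"{cfg.hidden_for(b.omics_name):>8}"
                f"{cfg.dropout_for(b.omics_name):>9.2f}"
                f"{mean_att[b.omics_name]:>18.3f}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path, extra_manifest: Optional[dict] = None) -> None:
        cfg_dict = self.model.config.to_dict()
        manifest = {
            "tool": "omicsfusion",
            "version": __version__,
            "omics_names": self._omics_names,
            "drug_ids": self._drug_ids,
            "seed": int(self.seed),
            "config": cfg_dict,
            "config_sha256": ofio.config_hash(cfg_dict),
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        ofio.save_checkpoint(self.subnetworks, self.attention, self.stats,
                             manifest, path)


def predict_from_checkpoint(ckpt: "ofio.Checkpoint", blocks: dict) -> pd.DataFrame:
    """Forward pass of a reloaded checkpoint on raw (unstandardized) blocks.

    ``blocks`` maps omics name -> OmicsMatrix with the checkpoint's feature
    ordering; the checkpoint's training standardization is applied.
    """
    names = ckpt.manifest["omics_names"]
    heads, cell_ids = [], None
    for name in names:
        if name not in blocks:
            raise ValueError(f"checkpoint expects omics block {name!r}")
        std, _ = standardize(blocks[name], ckpt.stats[name])
        cell_ids = std.cell_line_ids
        heads.append(subnetwork_forward(std.values, ckpt.subnetworks[name]))
    pred = fuse_and_predict(heads, ckpt.attention)
    return pd.DataFrame(pred, index=cell_ids, columns=ckpt.manifest["drug_ids"])
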