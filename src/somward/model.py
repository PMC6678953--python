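"""Model/Results facade over the SOM-Ward pipeline.

`SomWardModel` holds the data and the analysis configuration;
:meth:`SomWardModel.fit` trains the map, clusters it, and returns a
:class:`SomWardResults` carrying node assignments, cluster labels,
diagnostics and (when records are attached) statistical cluster
profiles with a ``summary()`` table.

    >>> model = SomWardModel.from_records(coded, vocab, k=16)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from . import ingest, profiling, som, ward
from .records import CodedRecord

__all__ = ["SomWardModel", "SomWardResults"]


class SomWardModel:
    """SOM-Ward clustering model over a binary disease-indicator matrix.

    Parameters
    ----------
    indicator_matrix : (n_records, n_categories) binary array.
    vocab : category labels naming the columns.
    k : number of clusters to cut the constrained dendrogram at
        (16 in the bundled study-replication configuration); ``k=None``
        lets :func:`ward.choose_k` suggest one.
    grid, schedule : map geometry and training schedule; defaulted from
        the data when omitted.
    records : optional coded records aligned with the matrix rows,
        enabling attribute profiling on the results object.
    """

    def __init__(
        self,
        indicator_matrix: np.ndarray,
        vocab: Sequence[str],
        k: int | None = 16,
        grid: som.SomGrid | None = None,
        schedule: som.TrainingSchedule | None = None,
        connectivity: int = 4,
        records: Sequence[CodedRecord] | None = None,
    ) -> None:
        self.endog = np.asarray(indicator_matrix, dtype=float)
        if self.endog.ndim != 2:
            raise ValueError("indicator matrix must be 2-D")
        if len(vocab) != self.endog.shape[1]:
            raise ValueError("vocabulary length must match matrix columns")
        self.vocab = tuple(vocab)
        self.k = k
        self.grid = grid
        self.schedule = schedule
        self.connectivity = connectivity
        self.records = list(records) if records is not None else None
        if self.records is not None and len(self.records) != self.endog.shape[0]:
            raise ValueError("records must align with matrix rows")

    @classmethod
    def from_records(
        cls,
        records: Sequence[CodedRecord],
        vocab: Sequence[str],
        **kwargs,
    ) -> "SomWardModel":
        matrix = ingest.build_indicator_matrix(records, vocab)
        return cls(matrix, vocab, records=records, **kwargs)

    def fit(
        self,
        seed: int | None = None,
        n_nodes: int = 400,
        n_restarts: int = 3,
    ) -> "SomWardResults":
        """Train the map, cluster it, and label every record.

        ``seed`` overrides the schedule's seed; it drives training-sample
        selection and random initialization, the only stochastic steps.
        ``n_restarts`` maps are trained from seeds derived deterministically
        from the master seed and the fit whose k-cluster partition attains
        the lowest within-cluster sum of squares (the Ward objective) is
        kept — map topology can trap a cluster in disconnected regions,
        and the Ward objective detects the resulting bad cuts where
        quantization error alone does not.
        """
        grid = self.grid or som.default_grid(self.endog, n_nodes=n_nodes)
        base_schedule = self.schedule or som.TrainingSchedule(
            sigma_start=max(grid.n_rows, grid.n_cols) / 2.0,
            sigma_end=0.5,
        )
        master = base_schedule.seed if seed is None else seed
        restart_seeds = [
            int(s) for s in
            np.random.SeedSequence(master).generate_state(max(n_restarts, 1)) % (2**31)
        ]

        best: tuple[float, SomWardResults] | None = None
        for rs in restart_seeds:
            schedule = som.TrainingSchedule(
                n_epochs=base_schedule.n_epochs,
                sigma_start=base_schedule.sigma_start,
                sigma_end=base_schedule.sigma_end,
                sample_size=base_schedule.sample_size,
                seed=rs,
            )
            som_model = som.train_batch(self.endog, grid, schedule)
            assignment = som.map_records(som_model, self.endog)
            k = self.k
            if k is None:
                # run the dendrogram to a single cluster, then cut at the jump
                full = ward.som_ward_cluster(
                    som_model, assignment, k=1, connectivity=self.connectivity
                )
                k = ward.choose_k(full.dendrogram)
            clusters = ward.som_ward_cluster(
                som_model, assignment, k=k, connectivity=self.connectivity
            )
            res = SomWardResults(model=self, som_model=som_model,
                                 assignment=assignment, clusters=clusters)
            sse = res.within_cluster_sse_
            if best is None or sse < best[0]:
                best = (sse, res)
        return best[1]


@dataclass
class SomWardResults:
    """Fitted map + clustering, with profiling and diagnostics attached."""

    model: SomWardModel
    som_model: som.SomModel
    assignment: som.NodeAssignment
    clusters: ward.ClusterModel

    @property
    def k(self) -> int:
        return self.clusters.k

    @cached_property
    def labels_(self) -> np.ndarray:
        """Per-record cluster label (via each record's BMU node)."""
        return ward.label_records(self.assignment, self.clusters)

    @cached_property
    def within_cluster_sse_(self) -> float:
        """Record-level within-cluster sum of squares at the final cut
        (the Ward objective; used to select among training restarts)."""
        X = self.model.endog
        labels = self.labels_
        sse = 0.0
        for cid in range(self.k):
            xc = X[labels == cid]
            if len(xc):
                sse += float(((xc - xc.mean(axis=0)) ** 2).sum())
        return sse

    @cached_property
    def quantization_error_(self) -> float:
        return som.quantization_error(self.som_model, self.model.endog, self.assignment)

    @cached_property
    def frame(self) -> pd.DataFrame:
        if self.model.records is None:
            raise ValueError("no records attached; profiling needs coded records")
        return profiling.records_frame(self.model.records)

    @cached_property
    def profiles(self) -> tuple[list[profiling.ClusterProfile], profiling.ClusterProfile]:
        return profiling.profile_clusters(self.frame, self.labels_)

    def component_plane(self, values: np.ndarray | str) -> tuple[np.ndarray, np.ndarray]:
        """Per-node mean of an attribute (by name, when records are
        attached, or as an explicit per-record array)."""
        if isinstance(values, str):
            if values in self.model.vocab:
                col = self.model.endog[:, self.model.vocab.index(values)]
            else:
                col = self.frame[values].to_numpy(dtype=float)
            values = col
        return som.component_plane(self.som_model, self.assignment, values)

    def summary(self) -> str:
        """Human-readable fit summary: geometry, diagnostics, clusters."""
        g = self.som_model.grid
        qe = self.quantization_error_
        trace = self.som_model.training_qe_trace
        lines = [
            "SOM-Ward clustering results",
            "===========================",
            f"Records:              {self.model.endog.shape[0]:,}",
            f"Disease categories:   {len(self.model.vocab)}",
            f"Map grid:             {g.n_rows} x {g.n_cols} ({g.n_nodes} nodes)",
            f"Quantization error:   {qe:.4f}"
            + (f" (training: {trace[0]:.4f} -> {trace[-1]:.4f})" if trace is not None else ""),
            f"Clusters (k):         {self.k}",
            "",
            f"{'cluster':>7} {'records':>10} {'share':>7}  top conditions",
        ]
        total = self.clusters.cluster_weights.sum()
        frame = None
        if self.model.records is not None:
            frame = self.frame
        for cid in range(self.k):
            w = self.clusters.cluster_weights[cid]
            top = ""
            if frame is not None:
                mask = self.labels_ == cid
                if mask.any():
                    ranked = profiling.top_k_conditions(frame, mask, k=3)
                    top = ", ".join(f"{c} ({p:.1f}%)" for c, p in ranked)
            lines.append(f"{cid:>7} {int(w):>10,} {100 * w / total:>6.1f}%  {top}")
        return "\n".join(lines)
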