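"""End-to-end orchestration: config in, artifact directory + manifest out.

A single YAML config drives synthesis (or file ingest), coding, SOM
training, constrained Ward clustering and profiling. One seed propagates
to every stochastic stage, so an identical config + seed reproduces
byte-identical artifacts. The manifest mirrors the record bookkeeping a
study report needs: parsed, malformed, omitted and usable counts per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, ingest, profiling, som, synthetic, ward
from .model import SomWardModel
from .records import CategoryMap

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    source: str = "synthetic"  # synthetic | mcod_file
    input_path: str | None = None
    schema_path: str | None = None
    category_map_path: str | None = None  # None -> bundled demo map
    n_records: int = 100_000
    grid: dict | None = None  # {"n_rows": .., "n_cols": ..}
    schedule: dict = field(default_factory=dict)
    n_nodes: int = 400
    k: int | None = 16
    connectivity: int = 4
    seed: int = 0
    significance: float = 0.01
    planes: tuple[str, ...] = ("age_years", "multimorbid")
    output_dir: str = "somward_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "planes" in cfg:
            cfg["planes"] = tuple(cfg["planes"])
        return cls(**cfg)

    def validate(self) -> None:
        if self.source not in ("synthetic", "mcod_file"):
            raise ValueError(f"unknown input source {self.source!r}")
        if self.source == "mcod_file":
            if not self.input_path or not Path(self.input_path).exists():
                raise ValueError(f"input file not found: {self.input_path!r}")
        if self.category_map_path and not Path(self.category_map_path).exists():
            raise ValueError(f"category map not found: {self.category_map_path!r}")


def run_pipeline(config: PipelineConfig, seed: int | None = None, k: int | None = ...) -> dict:
    """Execute all stages and return the run manifest (also written as
    ``manifest.json`` in the output directory).

    ``seed``/``k`` override the config when given. Any stage error aborts
    with the stage name; a manifest marked incomplete is still written.
    """
    if seed is not None:
        config.seed = seed
    if k is not ...:
        config.k = k
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "somward_version": __version__,
        "seed": config.seed,
        "status": "incomplete",
        "counts": {},
        "artifacts": [],
    }

    def _save(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    try:
        stage = "config"
        config.validate()

        stage = "category_map"
        if config.category_map_path:
            cmap = CategoryMap.load(config.category_map_path)
        else:
            cmap = synthetic.demo_category_map()
        vocab = cmap.category_vocabulary

        stage = "ingest" if config.source == "mcod_file" else "simulate"
        report = ingest.ParseReport()
        if config.source == "synthetic":
            spec = synthetic.default_benchmark_spec(
                n_records=config.n_records, seed=config.seed
            )
            raws, latent = synthetic.generate_population(spec)
            synthetic.write_records_csv(raws, _save("records.csv"))
            synthetic.write_labels_csv(raws, latent, _save("latent_labels.csv"))
            report.n_parsed = len(raws)
        else:
            schema = (
                ingest.ColumnSchema.from_yaml(config.schema_path)
                if config.schema_path
                else ingest.ColumnSchema.default()
            )
            raws = list(ingest.parse_mcod(config.input_path, schema, report))

        stage = "code"
        coded = [ingest.code_record(r, cmap) for r in raws]
        usable, omitted = ingest.filter_usable(coded)
        ingest.write_coded_csv(usable, _save("coded.csv"))
        manifest["counts"] = {
            "parsed": report.n_parsed,
            "malformed": report.n_malformed,
            "omitted": omitted,
            "usable": len(usable),
        }
        if not usable:
            raise ValueError("no usable records after filtering")

        stage = "train"
        grid = som.SomGrid(**config.grid) if config.grid else None
        sched_kwargs = dict(config.schedule)
        sched_kwargs.setdefault("seed", config.seed)
        if grid is not None:
            sched_kwargs.setdefault("sigma_start", max(grid.n_rows, grid.n_cols) / 2.0)
        schedule = som.TrainingSchedule(**sched_kwargs)
        model = SomWardModel.from_records(
            usable, vocab, k=config.k, grid=grid, schedule=schedule,
            connectivity=config.connectivity,
        )

        stage = "som_ward"
        res = model.fit(seed=config.seed, n_nodes=config.n_nodes)
        som.save_model(res.som_model, _save("som_header.yaml"), _save("som_codebook.csv"))
        ward.save_clusters(
            res.clusters, res.som_model.grid, res.assignment,
            _save("nodes.csv"), _save("dendrogram.csv"),
        )
        labels = res.labels_
        with open(_save("record_labels.csv"), "w") as fh:
            fh.write("record_id,cluster\n")
            for rec, lab in zip(usable, labels):
                fh.write(f"{rec.record_id},{int(lab)}\n")
        manifest["k"] = res.k
        manifest["quantization_error"] = round(res.quantization_error_, 10)
        manifest["cluster_sizes"] = [int(w) for w in res.clusters.cluster_weights]

        stage = "profile"
        profiles, global_profile = res.profiles
        profiling.profiles_to_frame(profiles, global_profile).to_csv(
            _save("profiles.csv"), index=False
        )
        with open(_save("population_table.txt"), "w") as fh:
            fh.write(profiling.format_population_table(global_profile) + "\n")

        stage = "planes"
        for attr in config.planes:
            plane, _n = res.component_plane(attr)
            np.savetxt(_save(f"plane_{attr}.csv"), plane, delimiter=",", fmt="%.10g")

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
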