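"""End-to-end runs: simulate -> spine metrics -> clustering test -> report.

``run_pipeline`` executes the selected stages in dependency order, writes
every table as CSV and a JSON summary for the Monte Carlo test, and records a
manifest (tool version, configuration hash, seeds, input checksums, per-stage
outputs).  Re-running with the same configuration and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import ClusteringConfig, monte_carlo_test, pair_statistics
from .io import (
    config_to_dict,
    file_checksum,
    read_spine_csv,
    write_isi_recording,
    write_mask_tiff,
    write_spine_csv,
)
from .isi import binocular_roi, fourier_response, ocular_dominance
from .spines import density_table, size_change_table, turnover_table
from .synthetic import (
    ISISimConfig,
    SpineSimConfig,
    simulate_isi_recording,
    simulate_spine_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

_STAGES = ("simulate", "metrics", "cluster", "isi")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "metrics", "cluster")
    spine_sim: SpineSimConfig = field(default_factory=SpineSimConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    isi_sim: ISISimConfig = field(default_factory=ISISimConfig)
    input_csv: Path | None = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # one root seed drives every stage unless stage configs override
        self.spine_sim = dataclasses.replace(self.spine_sim, seed=self.seed)
        self.clustering = dataclasses.replace(self.clustering, seed=self.seed)
        self.isi_sim = dataclasses.replace(self.isi_sim, seed=self.seed)


@dataclass
class RunManifest:
    """Provenance record for a pipeline run."""

    version: str
    seed: int
    config_hash: str
    stages: list[str]
    inputs: dict[str, str]
    outputs: dict[str, list[str]]

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def _config_hash(config: RunConfig) -> str:
    payload = {
        "seed": config.seed,
        "stages": list(config.stages),
        "spine_sim": config_to_dict(config.spine_sim),
        "clustering": config_to_dict(config.clustering),
        "isi_sim": config_to_dict(config.isi_sim),
    }
    canonical = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the selected stages, writing tables, summaries and a manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    inputs: dict[str, str] = {}
    data_csv = out / "spines.csv"

    if "simulate" in config.stages:
        dataset = simulate_spine_dataset(config.spine_sim)
        write_spine_csv(dataset, data_csv, config=config.spine_sim)
        outputs["simulate"] = [data_csv.name, data_csv.with_suffix(".json").name]
        logger.info(
            "simulated %d dendrites, %d spines",
            len(dataset.dendrites), dataset.n_spines,
        )
    else:
        source = config.input_csv or data_csv
        if not Path(source).exists():
            raise FileNotFoundError(
                f"no spine data at {source}; run the 'simulate' stage first "
                "or pass input_csv"
            )
        inputs["spine_csv"] = file_checksum(source)
        dataset = read_spine_csv(source)
        data_csv = Path(source)

    table = None
    if "metrics" in config.stages:
        window = config.clustering.window or dataset.post_sessions
        table = size_change_table(dataset, window=window)
        files = []
        for name, frame in (
            ("changes.csv", table.changes),
            ("spine_summary.csv", table.spines),
            ("turnover.csv", turnover_table(dataset)),
            ("density.csv", density_table(dataset)),
            ("excluded.csv", table.excluded),
        ):
            frame.to_csv(out / name, index=False)
            files.append(name)
        outputs["metrics"] = files
        logger.info(
            "metrics: %d spines, %d persistent",
            len(table.spines), int(table.spines["persistent"].sum()),
        )

    if "cluster" in config.stages:
        if table is None:
            summary_path = out / "spine_summary.csv"
            if not summary_path.exists():
                raise FileNotFoundError(
                    f"no spine summary at {summary_path}; run the 'metrics' "
                    "stage first"
                )
            import pandas as pd

            spines_df = pd.read_csv(summary_path)
        else:
            spines_df = table.spines
        stats = pair_statistics(spines_df, config.clustering)
        result = monte_carlo_test(spines_df, config.clustering)
        stats.pairs.to_csv(out / "pairs.csv", index=False)
        stats.per_dendrite.to_csv(out / "dendrite_fractions.csv", index=False)
        import pandas as pd

        hist = pd.DataFrame(result.shuffled)
        hist.to_csv(out / "mc_histograms.csv", index=False)
        summary = {
            "n_pairs": result.n_pairs,
            "n_dendrites": result.n_dendrites,
            "n_pools": result.n_pools,
            "seed": config.seed,
            "metrics": result.to_dict(),
        }
        (out / "cluster_summary.json").write_text(
            json.dumps(summary, indent=2)
        )
        outputs["cluster"] = [
            "pairs.csv", "dendrite_fractions.csv", "mc_histograms.csv",
            "cluster_summary.json",
        ]
        logger.info(
            "clustering: %d pairs over %d dendrites",
            result.n_pairs, result.n_dendrites,
        )

    if "isi" in config.stages:
        files = []
        maps = {}
        for eye in ("contra", "ipsi"):
            recording = simulate_isi_recording(config.isi_sim, eye=eye)
            write_isi_recording(recording, out, stem=f"isi_{eye}")
            files += [f"isi_{eye}.tif", f"isi_{eye}.json"]
            maps[eye] = fourier_response(recording).amplitude
        roi = binocular_roi(maps["ipsi"])
        od = ocular_dominance(maps["contra"], maps["ipsi"], roi)
        write_mask_tiff(roi, out / "roi.tif")
        (out / "odi.json").write_text(
            json.dumps(
                {
                    "ODI": od.odi,
                    "C_mean": od.c_mean,
                    "I_mean": od.i_mean,
                    "n_roi_pixels": od.n_roi_pixels,
                    "seed": config.seed,
                },
                indent=2,
            )
        )
        outputs["isi"] = files + ["roi.tif", "odi.json"]

    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config_hash=_config_hash(config),
        stages=list(config.stages),
        inputs=inputs,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
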