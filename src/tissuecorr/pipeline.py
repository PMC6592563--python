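"""Orchestration: tracks -> reconstruction -> distances -> pair table -> tests.

:func:`run_analysis` ties the library together for one dataset: reconstruct
the linear reporter signal from the two channels, locate cells and compute
normalised Euclidean distances, sample contact networks for median geodesic
distances, assemble the pair table, and run the juxtacrine / paracrine /
contact / network-free batteries.  Everything is deterministic given the
seed; every output file carries the config hash and seed in its header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, hdr, io, network, scores, signalling
from .errors import TissueCorrError

__all__ = ["PipelineConfig", "run_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one analysis run."""

    tracks_path: str
    out_dir: str
    seed: int = 0
    size_mean: float = 12.0  # um, Gamma diameter mean
    size_sd: float = 2.2  # um, Gamma diameter sd
    reference_diameter: float | None = None  # defaults to size_mean
    n_network_samples: int = 999
    n_boot: int = 999
    juxtacrine_windows: tuple = signalling.JUXTACRINE_DE_WINDOWS
    paracrine_windows: tuple = signalling.PARACRINE_DG_WINDOWS
    saturation_onset: float | None = None  # a.u.; None = auto-detect

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s done in %.2f s", name, t1 - t0)
    return t1


def run_analysis(config: PipelineConfig) -> dict:
    """Run the full analysis for one tracked dataset.

    Writes ``gfp.csv``, ``distances_euclidean.csv``, ``distances_geodesic.csv``,
    ``pairs.csv``, ``tests.json`` and ``summary.csv`` under ``config.out_dir``
    and returns the test results as a dict.  Aborts with a stage-named error
    on failure; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": io.config_hash(config.as_dict()), "seed": config.seed}
    t0 = time.perf_counter()

    stage = "load-tracks"
    try:
        if not Path(config.tracks_path).exists():
            raise TissueCorrError(f"tracks file not found: {config.tracks_path}")
        tracks = io.read_tracks_csv(config.tracks_path)
        t0 = _stage(stage, t0)

        stage = "reconstruct"
        cal = hdr.fit_linear_range(
            tracks["ch1"].to_numpy(),
            tracks["ch2"].to_numpy(),
            saturation_onset=config.saturation_onset,
        )
        gfp = tracks[["cell_id", "time_h"]].copy()
        gfp["gfp"] = hdr.reconstruct(
            tracks["ch1"].to_numpy(), tracks["ch2"].to_numpy(), cal
        )
        io.write_table(gfp, out / "gfp.csv", meta)
        t0 = _stage(stage, t0)

        stage = "geometry"
        ref = config.reference_diameter or config.size_mean
        d_e = geometry.euclidean_matrix(tracks, reference_diameter=ref)
        ids = d_e.cell_ids
        iu = np.triu_indices(len(ids), k=1)
        io.write_table(
            _long(ids, iu, {"d_e": d_e.values}), out / "distances_euclidean.csv", meta
        )
        t0 = _stage(stage, t0)

        stage = "network"
        _, centroids = geometry.centroids_from_tracks(tracks)
        d_g = network.median_geodesic(
            centroids,
            network.SizeDistribution(config.size_mean, config.size_sd),
            n_samples=config.n_network_samples,
            seed=config.seed,
        )
        io.write_table(
            _long(ids, iu, {"d_g_median": d_g.values,
                            "frac_disconnected": d_g.frac_disconnected}),
            out / "distances_geodesic.csv", meta,
        )
        t0 = _stage(stage, t0)

        stage = "pairs"
        wide = gfp.pivot_table(index="time_h", columns="cell_id", values="gfp")
        series = {cid: wide[cid].to_numpy() for cid in wide.columns}
        pairs = scores.build_pair_table(series, d_e, d_g, score="pearson")
        io.write_table(pairs, out / "pairs.csv", meta)
        n_inf = int(np.isinf(pairs["d_g"]).sum())
        logger.info("pair table: %d pairs, %d with disconnected d_g", len(pairs), n_inf)
        t0 = _stage(stage, t0)

        stage = "tests"
        specs = [signalling.TestSpec("network_free")]
        specs += [signalling.TestSpec("juxtacrine", w) for w in config.juxtacrine_windows]
        specs += [signalling.TestSpec("paracrine", w) for w in config.paracrine_windows]
        specs.append(signalling.TestSpec("contact"))
        results = {}
        for k, spec in enumerate(specs):
            res = signalling.run_test(
                pairs, spec, n_boot=config.n_boot, seed=config.seed + k
            )
            key = spec.mode + (f"_{spec.window}" if spec.window else "")
            results[key] = dataclasses.asdict(res)
        with open(out / "tests.json", "w") as fh:
            json.dump({"meta": meta, "results": results}, fh, indent=1, default=float)
        summary = [
            {"test": k, "slope": v["slope"], "p_one_sided": v["p_one_sided"],
             "n_pairs": v["n_pairs"]}
            for k, v in results.items()
        ]
        io.write_table(pd.DataFrame(summary), out / "summary.csv", meta)
        _stage(stage, t0)
    except TissueCorrError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        raise TissueCorrError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _long(ids, iu, columns: dict):
    data = {"cell_i": np.asarray(ids)[iu[0]], "cell_j": np.asarray(ids)[iu[1]]}
    data.update({name: mat[iu] for name, mat in columns.items()})
    return pd.DataFrame(data)
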