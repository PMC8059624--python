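"""Pipeline orchestration: configuration, readers/writers, run manifest.

Intermediates are plain CSV plus a JSON manifest (config echo, package
and library versions, input checksums) so a run is auditable and
reproducible from its output directory alone.  All floats are written
with ``repr`` round-trip precision, making reruns with the same seed
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .traits import expand_and_scale, gower_distance, load_trait_table, upgma, write_trait_table
from .diversity import compute_diversity, read_community_csv, write_community_csv
from .cwv import cwm_matrix, cwv_matrix, functional_variance_pc1
from .trends import fit_dispersion_model, region_specific_fits, model_summary_table
from .synthetic import SyntheticConfig, generate_species_pool, generate_survey, ground_truth

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Paths and switches for one pipeline run."""

    abundance_path: str
    traits_path: str
    traits_meta_path: str
    out_dir: str
    scale_columns: bool = False
    spatial: bool = False
    seed: int = 0
    log_level: str = "INFO"
    region_column: str = "region"
    year_column: str = "year"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_csv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index_label=index_label)


def write_manifest(out_dir: Path, cfg: dict, inputs: dict[str, str], outputs: list[str]) -> None:
    manifest = {
        "funcvar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg,
        "input_checksums": {k: _sha256(v) for k, v in inputs.items() if Path(v).exists()},
        "outputs": sorted(outputs),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_to_dir(cfg: SyntheticConfig, out_dir: str) -> dict[str, str]:
    """Run the generator and write abundance.csv, traits.csv, traits.yml,
    stations.csv and ground_truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tt, pools = generate_species_pool(cfg)
    cm = generate_survey(cfg, pools)
    write_trait_table(tt, str(out / "traits.csv"), str(out / "traits.yml"))
    write_community_csv(cm, str(out / "abundance.csv"))
    stations = cm.station_meta.copy()
    stations.index.name = "station_id"
    stations.to_csv(out / "stations.csv")
    pools.rename_axis("species_id").to_csv(out / "species_pools.csv")
    gt = ground_truth(cfg)
    gt["boreal_occupancy_in_arctic"] = {str(k): v for k, v in gt["boreal_occupancy_in_arctic"].items()}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cfg.to_yaml(str(out / "synthetic_config.yml"))
    return {
        "abundance": str(out / "abundance.csv"),
        "traits": str(out / "traits.csv"),
        "traits_meta": str(out / "traits.yml"),
    }


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute the full analysis chain and write every output table.

    Stages: trait ingestion and Gower/UPGMA -> diversity indices ->
    CWM/CWV matrices and functional-variance PCA -> mixed-effect trend
    models.  Returns a name -> path map of the written artifacts.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "trait ingestion"
    try:
        tt = load_trait_table(cfg.traits_path, cfg.traits_meta_path)
        cm = read_community_csv(cfg.abundance_path)
        dist = gower_distance(tt)
        tree = upgma(dist)
        X = expand_and_scale(tt)
        write_csv(dist.to_frame(), out / "gower_distance.csv", index_label="species_id")

        stage = "diversity indices"
        div = compute_diversity(cm, tt, distance=dist, tree=tree)
        write_csv(div.per_station, out / "diversity_per_station.csv", index_label="station_id")
        div.regional_means.to_csv(out / "diversity_regional.csv", index=False,
                                  float_format=FLOAT_FMT)

        stage = "functional variance"
        M = cwm_matrix(cm.drop_empty_stations(), X)
        fv = functional_variance_pc1(cm, tt, scale_columns=cfg.scale_columns)
        write_csv(M, out / "cwm.csv", index_label="station_id")
        V = cwv_matrix(cm.drop_empty_stations(), X)
        write_csv(V, out / "cwv.csv", index_label="station_id")
        write_csv(fv.pca_result.scores, out / "pca_scores.csv", index_label="station_id")
        write_csv(fv.pca_result.loadings, out / "pca_loadings.csv", index_label="trait")
        expl = pd.DataFrame(
            {
                "component": fv.pca_result.scores.columns,
                "explained_fraction": fv.pca_result.explained,
            }
        )
        expl.to_csv(out / "explained.csv", index=False, float_format=FLOAT_FMT)

        trends_tab = div.per_station.join(
            fv.per_station["PC1"], how="inner"
        )
        regional = (
            trends_tab.groupby(["region", "year"], sort=True)[["PC1", "Q", "FRic", "S", "J"]]
            .mean()
            .reset_index()
            .rename(columns={"PC1": "mean_PC1", "Q": "mean_Q", "FRic": "mean_FRic",
                             "S": "mean_S", "J": "mean_J"})
        )
        regional.to_csv(out / "regional_trends.csv", index=False, float_format=FLOAT_FMT)

        stage = "trend models"
        fits = [fit_dispersion_model(trends_tab, scope="all", spatial=cfg.spatial)]
        fits.extend(region_specific_fits(trends_tab, spatial=cfg.spatial).values())
        model_summary_table(fits).to_csv(out / "model_summary.csv", index=False,
                                         float_format=FLOAT_FMT)
    except Exception:
        logger.error("pipeline failed during stage: %s", stage)
        raise
    outputs = [
        "gower_distance.csv", "diversity_per_station.csv", "diversity_regional.csv",
        "cwm.csv", "cwv.csv", "pca_scores.csv", "pca_loadings.csv", "explained.csv",
        "regional_trends.csv", "model_summary.csv",
    ]
    write_manifest(
        out,
        asdict(cfg),
        {
            "abundance": cfg.abundance_path,
            "traits": cfg.traits_path,
            "traits_meta": cfg.traits_meta_path,
        },
        outputs,
    )
    return {name: str(out / name) for name in outputs + ["run_manifest.json"]}
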