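"""Plain-text readers/writers and run manifests.

Datasets are small (hundreds of records), and an epidemiology audience needs
to audit inputs and outputs by eye, so everything is CSV/JSON/YAML: records
and omics as CSV, the synthetic truth as JSON, posterior draws as one CSV per
parameter block (chain- and draw-indexed), plus a JSON manifest recording the
configuration hash, seeds, input digests and software version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import CrossoverDataset, DatasetSchemaError, SyntheticTruth
from .models import PosteriorDraws

log = logging.getLogger("trapme")

RECORDS_FILE = "records.csv"
OMICS_FILE = "omics.csv"
TRUTH_FILE = "truth.json"
MANIFEST_FILE = "manifest.json"


def write_dataset(ds: CrossoverDataset, out_dir, truth: SyntheticTruth | None = None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / RECORDS_FILE,
        "omics": out / OMICS_FILE,
    }
    ds.records.to_csv(paths["records"], index_label="record_id")
    ds.omics.to_csv(paths["omics"], index_label="feature_id")
    if truth is not None:
        paths["truth"] = out / TRUTH_FILE
        truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_dataset(path) -> CrossoverDataset:
    """Read and validate a long-format dataset directory (records + omics CSV)."""
    path = Path(path)
    rec_path = path / RECORDS_FILE
    om_path = path / OMICS_FILE
    if not rec_path.exists() or not om_path.exists():
        raise FileNotFoundError(f"expected {RECORDS_FILE} and {OMICS_FILE} in {path}")
    records = pd.read_csv(rec_path, index_col="record_id")
    omics = pd.read_csv(om_path, index_col="feature_id")
    ds = CrossoverDataset(records=records, omics=omics)
    ds.validate()  # raises DatasetSchemaError with row/column context
    return ds


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path) / TRUTH_FILE if Path(path).is_dir() else path)


def write_draws(draws: PosteriorDraws, out_dir) -> dict:
    """One CSV per parameter block: columns (chain, draw, idx..., value)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in draws.params.items():
        C = arr.shape[0]
        flat = arr.reshape(C * arr.shape[1], -1) if arr.ndim > 1 else arr.reshape(C, -1)
        if arr.ndim >= 2:
            idx = pd.MultiIndex.from_product(
                [range(C), range(arr.shape[1])], names=["chain", "draw"]
            )
            df = pd.DataFrame(flat, index=idx)
            df.columns = [f"v{i}" for i in range(df.shape[1])]
        else:
            df = pd.DataFrame({"v0": arr})
        p = out / f"{name}.csv"
        header = f"# shape={arr.shape}\n"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh)
        paths[name] = str(p)
    meta = {
        "variant": draws.spec.variant,
        "feature_ids": draws.feature_ids,
        "pollutant_ids": draws.pollutant_ids,
        "covariate_names": draws.covariate_names,
        "seed": draws.mcmc.seed,
        "n_chains": draws.mcmc.n_chains,
        "n_iter": draws.mcmc.n_iter,
        "n_burnin": draws.mcmc.n_burnin,
        "thin": draws.mcmc.thin,
        "warnings": draws.warnings,
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    paths["run_meta"] = str(out / "run_meta.json")
    return paths


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def write_manifest(out_dir, config: dict, seed: int, inputs: dict | None = None) -> str:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "config": json.loads(json.dumps(config, default=str)),
        "seed": seed,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "input_digests": {
            name: _digest(Path(p)) for name, p in (inputs or {}).items() if Path(p).exists()
        },
    }
    path = out / MANIFEST_FILE
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return str(path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
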